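"""Long-term live-cell induction analysis.

Assembles per-timepoint masked ratios into series, normalizes an induced
series to its vehicle control (which cancels shared handling artifacts such
as the brief ratio transient after solution application), fits the delayed
sigmoid rise, and derives biogenesis-latency metrics: the onset delay
``t_del``, the half-maximal time ``t_half``, and the 20-80% rise interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import DomainError, FitResult, fit_sigmoid, sigmoid_metrics

__all__ = ["TimecourseSeries", "normalize_to_control", "fit_latency"]


@dataclass
class TimecourseSeries:
    """Mean ratio (± sem over imaging locations) vs. time in minutes.

    Timepoints are relative to induction at ``t = 0`` and must be strictly
    increasing.
    """

    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.t.shape == self.mean.shape == self.sem.shape):
            raise DomainError("t, mean, sem must have matching shapes")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("timepoints must be strictly increasing")
        if np.any(self.sem < 0):
            raise DomainError("sem must be non-negative")


def normalize_to_control(
    induced: TimecourseSeries,
    control: TimecourseSeries,
    tol: float | None = None,
) -> TimecourseSeries:
    """Relative change of induced over control, percent, per timepoint.

    Grids must match to within ``tol`` (default: one sampling interval).
    Uncertainty is combined in quadrature to first order.
    """
    if induced.t.size != control.t.size:
        raise DomainError("series have different lengths")
    if tol is None:
        tol = float(np.median(np.diff(induced.t))) if induced.t.size > 1 else 0.0
    if np.any(np.abs(induced.t - control.t) > tol):
        raise DomainError(f"time grids misaligned beyond tolerance {tol} min")
    ratio = induced.mean / control.mean
    rel = 100.0 * (ratio - 1.0)
    sem = 100.0 * np.abs(ratio) * np.sqrt(
        (induced.sem / induced.mean) ** 2 + (control.sem / control.mean) ** 2
    )
    return TimecourseSeries(induced.t, rel, sem,
                            label=f"{induced.label} vs {control.label}".strip())


def fit_latency(series: TimecourseSeries, mask_initial: int = 2) -> FitResult:
    """Fit the delayed sigmoid to a normalized relative-change series.

    The first ``mask_initial`` post-induction samples are excluded from the
    fit (handling transient).  On success ``extra['metrics']`` holds the
    closed-form latency metrics and ``extra['onset_window']`` the
    ``(t_del, t_20)`` interval; a flat series is flagged ``no_induction``.
    """
    t, y = series.t, series.mean
    post = np.nonzero(t >= 0)[0]
    drop = set(post[:mask_initial].tolist())
    keep = np.array([i for i in range(t.size) if i not in drop])
    res = fit_sigmoid(t[keep], y[keep])
    if "no_amplitude" in res.flags:
        res.flags.append("no_induction")
        return res
    metrics = sigmoid_metrics(res.params)
    res.extra["metrics"] = metrics
    res.extra["onset_window"] = (res.params.t_del, metrics["t_20"])
    return res
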