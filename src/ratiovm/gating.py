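"""Post-extraction quality control of per-cell records.

Three gates, applied after fluorescence extraction and before population
statistics:

* **Red expression gate** — removes non-transfected / low-expressing cells
  and very bright cells whose green signal risks saturation, by cutoffs on
  the red reference intensity (explicit counts or quantiles).
* **Background-offset optimization** — if the green background was
  under/over-subtracted, the per-cell ratio acquires a spurious dependence
  on expression level.  The residual green offset is found by scanning
  candidate offsets and minimizing the squared slope of median ratio vs.
  red intensity (slope^2 profile).
* **DNA-content (cell-cycle) gate** — keeps cells between the G0/G1 and
  G2/M peaks of the nuclear-stain intensity histogram; signal below the
  G0/G1 peak is debris, signal above the G2/M peak non-separated doublets.

Every gate returns an audit whose per-reason counts sum to the input count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .models import DomainError

__all__ = [
    "GateConfig",
    "gate_by_red",
    "optimize_background_offset",
    "gate_by_cell_cycle",
]


@dataclass
class GateConfig:
    """Red-gate thresholds and cell-cycle gate settings.

    When ``f_red_lo``/``f_red_hi`` are None the quantile pair is used and
    resolved to concrete counts at gating time (echoed in the audit).
    """

    f_red_lo: float | None = None
    f_red_hi: float | None = None
    f_red_lo_q: float = 0.05
    f_red_hi_q: float = 0.99
    cc_gate_enabled: bool = True
    cc_half_width: float = 0.4
    background_green_offsets: tuple = ()

    def __post_init__(self):
        if self.f_red_lo is not None and self.f_red_hi is not None:
            if not (self.f_red_lo < self.f_red_hi):
                raise DomainError("f_red_lo must be < f_red_hi")
        if not (0 <= self.f_red_lo_q < self.f_red_hi_q <= 1):
            raise DomainError("quantile gates must satisfy 0 <= lo < hi <= 1")
        offs = tuple(self.background_green_offsets)
        if any(not np.isfinite(o) for o in offs):
            raise DomainError("offset grid must be finite")
        if list(offs) != sorted(offs):
            raise DomainError("offset grid must be ordered")


def gate_by_red(records: pd.DataFrame, cfg: GateConfig) -> tuple[pd.DataFrame, dict]:
    """Keep records with f_red strictly inside the gates and not saturated.

    Removal reasons are counted with precedence saturated > low > high, so
    the audit counts sum exactly to the input count.
    """
    if len(records) == 0:
        raise DomainError("records must be non-empty")
    f_red = records["f_red"].to_numpy(dtype=float)
    lo = cfg.f_red_lo if cfg.f_red_lo is not None else float(
        np.quantile(f_red, cfg.f_red_lo_q)
    )
    hi = cfg.f_red_hi if cfg.f_red_hi is not None else float(
        np.quantile(f_red, cfg.f_red_hi_q)
    )
    saturated = (
        records["saturated"].to_numpy(dtype=bool)
        if "saturated" in records
        else np.zeros(len(records), dtype=bool)
    )
    low = ~saturated & (f_red <= lo)
    high = ~saturated & ~low & (f_red >= hi)
    keep = ~(saturated | low | high)
    audit = {
        "gate": "f_red",
        "f_red_lo": lo,
        "f_red_hi": hi,
        "n_input": int(len(records)),
        "n_removed_saturated": int(saturated.sum()),
        "n_removed_low_f_red": int(low.sum()),
        "n_removed_high_f_red": int(high.sum()),
        "n_retained": int(keep.sum()),
    }
    return records.loc[keep].copy(), audit


def optimize_background_offset(
    records: pd.DataFrame,
    offsets,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Residual green background offset minimizing the slope^2 profile.

    For each candidate offset ``b`` the ratios ``(f_green - b)/f_red`` are
    binned by ``f_red`` (equal-count bins), the per-bin medians are fit with
    a line against the bin-mean red intensity, and the squared slope is
    recorded.  A correctly subtracted background makes the median ratio
    independent of expression level, so slope^2 is minimized at the true
    residual offset.
    """
    offsets = np.asarray(list(offsets), dtype=float)
    if offsets.size == 0:
        raise DomainError("offset grid is empty")
    if len(records) < 200:
        raise DomainError("need >= 200 records for offset optimization")
    f_red = records["f_red"].to_numpy(dtype=float)
    f_green = records["f_green"].to_numpy(dtype=float)
    try:
        bins = pd.qcut(f_red, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise DomainError(f"degenerate f_red binning: {exc}")
    n_eff = int(pd.Series(bins).nunique())
    if n_eff < 5:
        raise DomainError(
            f"degenerate binning: only {n_eff} distinct f_red bins "
            f"(requested {n_bins}); records span too little f_red range"
        )
    bin_red = np.array([f_red[bins == b].mean() for b in range(n_eff)])
    slope2 = np.empty(offsets.size)
    for i, b in enumerate(offsets):
        ratio = (f_green - b) / f_red
        med = np.array([np.median(ratio[bins == k]) for k in range(n_eff)])
        slope = np.polyfit(bin_red, med, 1)[0]
        slope2[i] = slope**2
    best = float(offsets[int(np.argmin(slope2))])
    profile = pd.DataFrame({"offset": offsets, "slope2": slope2})
    return best, profile


def gate_by_cell_cycle(
    records: pd.DataFrame, half_width: float = 0.4
) -> tuple[pd.DataFrame, dict]:
    """DNA-content gate from the modes of the nuclear-stain intensity.

    Detects the G0/G1 and G2/M peaks of the f_blue distribution by Gaussian
    kernel density (Silverman bandwidth) peak finding and retains records
    with ``f_blue`` in ``[G1*(1-w), G2*(1+w)]``.  A unimodal histogram falls
    back to ``[peak*(1-w), 2*peak*(1+w)]`` with a warning.
    """
    if len(records) == 0:
        raise DomainError("records must be non-empty")
    if len(records) < 300:
        raise DomainError("need >= 300 records for cell-cycle gating")
    f_blue = records["f_blue"].to_numpy(dtype=float)
    fallback = False
    if np.ptp(f_blue) == 0:
        g1 = g2 = float(f_blue[0])
        fallback = True
    else:
        kde = gaussian_kde(f_blue, bw_method="silverman")
        grid = np.linspace(f_blue.min(), f_blue.max(), 512)
        density = kde(grid)
        idx, props = find_peaks(density, prominence=0.02 * density.max())
        peaks = grid[idx]
        if peaks.size == 0:
            g1 = g2 = float(grid[int(np.argmax(density))])
            fallback = True
        else:
            heights = density[idx]
            g1 = float(peaks[int(np.argmax(heights))])
            # G2/M: most prominent peak near twice the G1 position
            cand = [
                (props["prominences"][k], float(p))
                for k, p in enumerate(peaks)
                if 1.6 * g1 <= p <= 2.5 * g1
            ]
            if cand:
                g2 = max(cand)[1]
            else:
                g2 = g1
                fallback = True
    if fallback:
        warnings.warn(
            "f_blue distribution not bimodal; using single-peak fallback gate",
            stacklevel=2,
        )
        lo, hi = g1 * (1.0 - half_width), 2.0 * g1 * (1.0 + half_width)
    else:
        lo, hi = g1 * (1.0 - half_width), g2 * (1.0 + half_width)
    below = f_blue < lo
    above = ~below & (f_blue > hi)
    keep = ~(below | above)
    audit = {
        "gate": "cell_cycle",
        "g1_peak": g1,
        "g2_peak": g2 if not fallback else 2.0 * g1,
        "fallback_unimodal": fallback,
        "f_blue_lo": lo,
        "f_blue_hi": hi,
        "n_input": int(len(records)),
        "n_removed_debris": int(below.sum()),
        "n_removed_doublet": int(above.sum()),
        "n_retained": int(keep.sum()),
    }
    return records.loc[keep].copy(), audit
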