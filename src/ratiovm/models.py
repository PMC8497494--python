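"""Closed-form models for ratiometric voltage-indicator analysis.

A ratiometric GEVI (genetically encoded voltage indicator) reports membrane
potential through the ratio of a voltage-sensitive green channel to a
voltage-insensitive red reference channel.  The steady-state ratio follows a
Boltzmann-type sigmoid of the membrane potential ``Vm``::

    r(Vm) = R_max * {1 - (dr/100) / (1 + exp(-(Vm - V_half)/k_s))}

with maximum ratio ``R_max``, maximal relative change ``dr`` (percent),
midpoint voltage ``V_half`` (mV) and slope factor ``k_s`` (mV).  This module
provides the forward model, its closed-form inversion (ratio -> Vm),
calibrated parameter sets for the rASAP and rArc sensors, the
double-exponential step-response kinetics model, the Nernst equilibrium
potential, and a delayed cubic-exponential sigmoid used to describe slow
induction time courses — together with least-squares fitting routines for
each.

Sign conventions
----------------
With ``k_s > 0`` the sigmoid term increases with depolarization, so the ratio
decreases with depolarization when ``dr`` and ``k_s`` share a sign.  The
same curve admits a mirrored parameterization (see
:meth:`BoltzmannParams.canonical`); canonical sensor calibrations are stored
so that depolarization lowers the modeled ratio, matching the observed
responses to gramicidin (depolarizing, ratio drops) and Kir2.1
(hyperpolarizing, ratio rises).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit, logit

__all__ = [
    "R_GAS",
    "FARADAY",
    "DomainError",
    "CalibrationRangeError",
    "FitConvergenceError",
    "BoltzmannParams",
    "KineticsParams",
    "SigmoidParams",
    "NernstConditions",
    "FitResult",
    "CALIBRATIONS",
    "boltzmann_ratio",
    "boltzmann_slope",
    "invert_boltzmann",
    "estimate_population_vm",
    "fit_boltzmann",
    "double_exp_response",
    "fit_double_exp",
    "nernst_potential",
    "sigmoid_time_course",
    "sigmoid_metrics",
    "fit_sigmoid",
    "calibration_to_dict",
    "calibration_from_dict",
]

R_GAS = 8.314  # J K^-1 mol^-1
FARADAY = 96485.0  # C mol^-1

# convergence policy shared by all fits: tight relative tolerance with a
# generous function-evaluation budget (the 4-parameter Boltzmann is sloppy
# on noisy data and needs many evaluations to meet the tolerance)
_MAXFEV = 50_000
_XTOL = 1e-10


class DomainError(ValueError):
    """Input outside the mathematical domain of a model."""


class CalibrationRangeError(ValueError):
    """Ratio outside the attainable range of a calibration curve."""

    def __init__(self, message: str, interval: tuple[float, float]):
        super().__init__(message)
        self.interval = interval


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the initialization used."""

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = p0


@dataclass(frozen=True)
class BoltzmannParams:
    """Boltzmann calibration of a ratiometric voltage sensor.

    Parameters
    ----------
    r_max : dimensionless maximum ratio (> 0).
    delta_r : maximal relative change of the ratio, percent.
    v_half : midpoint voltage, mV.
    k_s : slope factor, mV (non-zero).
    orientation_note : free-text record of any sign correction applied
        relative to a printed/source parameter set.
    """

    r_max: float
    delta_r: float
    v_half: float
    k_s: float
    orientation_note: str = ""

    def __post_init__(self):
        if not (self.r_max > 0):
            raise DomainError(f"r_max must be > 0, got {self.r_max}")
        if self.k_s == 0:
            raise DomainError("k_s must be non-zero")

    def ratio_limits(self) -> tuple[float, float]:
        """Open interval of attainable ratios (asymptote pair, sorted)."""
        a = self.r_max
        b = self.r_max * (1.0 - self.delta_r / 100.0)
        return (min(a, b), max(a, b))

    def canonical(self) -> "BoltzmannParams":
        """Equivalent representation with ``delta_r > 0``.

        ``(r_max, dr, k_s)`` and ``(r_max*(1-dr/100), -100*dr/(100-dr),
        -k_s)`` describe the same curve; this degeneracy is resolved by
        always reporting the positive-``delta_r`` member of the pair.
        """
        if self.delta_r >= 0:
            return self
        d = self.delta_r
        return replace(
            self,
            r_max=self.r_max * (1.0 - d / 100.0),
            delta_r=-100.0 * d / (100.0 - d),
            k_s=-self.k_s,
        )


@dataclass(frozen=True)
class KineticsParams:
    """Double-exponential step-response parameters.

    Relative amplitudes sum to 1; ``tau_fast < tau_slow`` (both ms);
    ``delta_r`` is the total relative fluorescence change in percent.
    """

    a_fast: float
    a_slow: float
    tau_fast: float
    tau_slow: float
    delta_r: float

    def __post_init__(self):
        if abs(self.a_fast + self.a_slow - 1.0) > 1e-9:
            raise DomainError("a_fast + a_slow must equal 1")
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise DomainError("time constants must be positive")
        if not (self.tau_fast < self.tau_slow):
            raise DomainError("tau_fast must be smaller than tau_slow")


@dataclass(frozen=True)
class SigmoidParams:
    """Delayed cubic-exponential sigmoid for slow induction time courses.

    The model is flat at ``y0`` until the delay ``t_del`` (min) and rises
    with time constant ``tau`` (min) toward ``y_max``.
    """

    y0: float
    y_max: float
    t_del: float
    tau: float

    def __post_init__(self):
        if not (self.tau > 0):
            raise DomainError("tau must be positive")


@dataclass(frozen=True)
class NernstConditions:
    """K+ concentrations (mM) and temperature (K) for the Nernst potential."""

    k_out: float
    k_in: float
    temperature: float = 310.15

    def __post_init__(self):
        if not (self.k_out > 0 and self.k_in > 0):
            raise DomainError("concentrations must be positive")
        if not (self.temperature > 0):
            raise DomainError("temperature must be positive")


@dataclass
class FitResult:
    """Container for fitted parameters plus diagnostics."""

    params: object
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    flags: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Boltzmann calibration
# ---------------------------------------------------------------------------


def _sigmoid_term(v_m, params: BoltzmannParams):
    return expit((np.asarray(v_m, dtype=float) - params.v_half) / params.k_s)


def boltzmann_ratio(v_m, params: BoltzmannParams):
    """Model ratio at membrane potential ``v_m`` (mV).

    Accepts scalars or arrays; raises :class:`DomainError` on non-finite
    voltages.
    """
    v = np.asarray(v_m, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DomainError("v_m must be finite")
    out = params.r_max * (1.0 - (params.delta_r / 100.0) * _sigmoid_term(v, params))
    return out if out.ndim else float(out)


def boltzmann_slope(v_m, params: BoltzmannParams):
    """Analytic derivative d(ratio)/dVm in ratio units per mV."""
    s = _sigmoid_term(v_m, params)
    out = -params.r_max * (params.delta_r / 100.0) * s * (1.0 - s) / params.k_s
    return out if np.ndim(out) else float(out)


def invert_boltzmann(ratio: float, params: BoltzmannParams) -> float:
    """Unique ``v_m`` (mV) with ``boltzmann_ratio(v_m) == ratio``.

    Closed-form logit inversion.  ``ratio`` must lie strictly between the
    two asymptotes of the calibration curve.
    """
    if params.delta_r == 0:
        raise CalibrationRangeError(
            "flat calibration (delta_r = 0) cannot be inverted", params.ratio_limits()
        )
    lo, hi = params.ratio_limits()
    s = (1.0 - ratio / params.r_max) * 100.0 / params.delta_r
    if not (0.0 < s < 1.0):
        raise CalibrationRangeError(
            f"ratio {ratio:.6g} is outside the attainable open interval "
            f"({lo:.6g}, {hi:.6g})",
            (lo, hi),
        )
    return params.v_half + params.k_s * float(logit(s))


def estimate_population_vm(
    median_sample: float,
    median_reference: float,
    params: BoltzmannParams,
    reference_vm: float = 0.0,
) -> float:
    """Population Vm from a sample median and a reference median.

    The calibration is rescaled so that its value at ``reference_vm`` maps
    to ``median_reference`` (e.g. gramicidin-depolarized cells at 0 mV),
    then inverted at ``median_sample``.
    """
    if not (median_sample > 0 and median_reference > 0):
        raise DomainError("medians must be positive")
    scaled = (median_sample / median_reference) * boltzmann_ratio(reference_vm, params)
    return invert_boltzmann(scaled, params)


def fit_boltzmann(v, r, sigma=None) -> FitResult:
    """Least-squares Boltzmann fit of ratio vs. voltage data.

    Requires at least 5 distinct voltages.  A constant-ratio input returns a
    flat curve (``delta_r = 0``) flagged ``unidentifiable`` instead of
    failing.  Because of the sign-pair degeneracy, recovered parameters
    should be compared through :meth:`BoltzmannParams.canonical`.
    """
    v = np.asarray(v, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.unique(v).size < 5:
        raise DomainError("need >= 5 distinct voltages")
    if np.ptp(r) <= 1e-12 * max(1.0, np.abs(r).max()):
        p = BoltzmannParams(float(np.mean(r)), 0.0, float(np.median(v)),
                            max(np.ptp(v) / 4.0, 1.0),
                            orientation_note="degenerate fit")
        return FitResult(p, flags=["unidentifiable"], residual_norm=0.0)

    order = np.argsort(v)
    vs, rs = v[order], r[order]
    r_lo_v = float(np.mean(rs[:2]))   # ratio on the hyperpolarized side
    r_hi_v = float(np.mean(rs[-2:]))  # ratio on the depolarized side
    # treat the low-voltage side as the s->0 asymptote (k_s > 0 convention)
    r_max0 = r_lo_v if r_lo_v != 0 else 1.0
    d0 = 100.0 * (1.0 - r_hi_v / r_max0)
    # quartile crossings for midpoint / steepness starting values
    lev25 = r_lo_v + 0.25 * (r_hi_v - r_lo_v)
    lev75 = r_lo_v + 0.75 * (r_hi_v - r_lo_v)
    v25 = float(np.interp(lev25, rs if rs[0] < rs[-1] else rs[::-1],
                          vs if rs[0] < rs[-1] else vs[::-1]))
    v75 = float(np.interp(lev75, rs if rs[0] < rs[-1] else rs[::-1],
                          vs if rs[0] < rs[-1] else vs[::-1]))
    vh0 = 0.5 * (v25 + v75)
    k0 = max(abs(v75 - v25) / 2.197, 1e-3)
    p0 = (r_max0, d0, vh0, k0)

    def model(vv, r_max, d, vh, ks):
        return r_max * (1.0 - (d / 100.0) * expit((vv - vh) / ks))

    try:
        popt, pcov = curve_fit(
            model, v, r, p0=p0, sigma=sigma, maxfev=_MAXFEV,
            xtol=_XTOL, ftol=_XTOL,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitConvergenceError(f"Boltzmann fit did not converge: {exc}", p0=p0)
    perr = np.sqrt(np.diag(pcov))
    resid = r - model(v, *popt)
    params = BoltzmannParams(*popt, orientation_note="fitted")
    return FitResult(
        params,
        stderr=dict(zip(("r_max", "delta_r", "v_half", "k_s"), perr)),
        residual_norm=float(np.linalg.norm(resid)),
        extra={"p0": p0},
    )


# ---------------------------------------------------------------------------
# Step-response kinetics
# ---------------------------------------------------------------------------


def double_exp_response(t, params: KineticsParams):
    """Normalized fluorescence after a voltage step at ``t = 0`` (ms)."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise DomainError("t must be >= 0")
    rise = params.a_fast * (1.0 - np.exp(-tt / params.tau_fast)) + params.a_slow * (
        1.0 - np.exp(-tt / params.tau_slow)
    )
    out = 1.0 - (params.delta_r / 100.0) * rise
    return out if out.ndim else float(out)


def fit_double_exp(t, f) -> FitResult:
    """Constrained double-exponential fit (``a_fast + a_slow = 1``).

    The fit parameterizes (a_fast, tau_fast, tau_slow, delta_r) and orders
    the time constants afterwards.  Near-collapse of the two time constants
    triggers a single-exponential fallback flagged ``single_exponential``.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size < 50:
        raise DomainError("need >= 50 samples")

    d0 = 100.0 * (1.0 - float(np.mean(f[-max(5, t.size // 50):])))
    if d0 == 0:
        d0 = 1.0
    g = np.clip((1.0 - f) / (d0 / 100.0), 0.0, None)
    tf0 = _first_crossing(t, g, 0.4) / 0.7
    ts0 = _first_crossing(t, g, 0.9) / 1.2
    tf0 = max(tf0, t[1] if t.size > 1 else 1e-3)
    ts0 = max(ts0, 3.0 * tf0)
    p0 = (0.6, tf0, ts0, d0)

    def model(tt, a_f, tau_f, tau_s, d):
        return 1.0 - (d / 100.0) * (
            a_f * (1.0 - np.exp(-tt / tau_f)) + (1.0 - a_f) * (1.0 - np.exp(-tt / tau_s))
        )

    bounds = ([0.0, 1e-9, 1e-9, -1e4], [1.0, np.inf, np.inf, 1e4])
    try:
        popt, pcov = curve_fit(model, t, f, p0=p0, bounds=bounds,
                               maxfev=_MAXFEV, xtol=_XTOL, ftol=_XTOL)
    except RuntimeError as exc:
        raise FitConvergenceError(f"double-exponential fit did not converge: {exc}",
                                  p0=p0)
    a_f, tau_f, tau_s, d = popt
    perr = dict(zip(("a_fast", "tau_fast", "tau_slow", "delta_r"),
                    np.sqrt(np.diag(pcov))))
    if tau_f > tau_s:  # enforce ordering convention
        tau_f, tau_s = tau_s, tau_f
        a_f = 1.0 - a_f
    flags = []
    if tau_s / tau_f < 1.05:
        # indistinguishable time constants: report a single exponential
        flags.append("single_exponential")
        tau = math.sqrt(tau_f * tau_s)
        params = KineticsParams(1.0, 0.0, tau, 1.5 * tau, d)
    else:
        if a_f < 0.01:
            flags.append("single_exponential")
            a_f = 0.0
        elif a_f > 0.99:
            flags.append("single_exponential")
            a_f = 1.0
        params = KineticsParams(a_f, 1.0 - a_f, tau_f, tau_s, d)
    resid = f - model(t, *popt)
    return FitResult(params, stderr=perr,
                     residual_norm=float(np.linalg.norm(resid)),
                     flags=flags, extra={"p0": p0})


def _first_crossing(t, g, level):
    idx = np.nonzero(g >= level)[0]
    if idx.size == 0:
        return float(t[-1])
    return float(t[idx[0]]) if idx[0] > 0 else float(t[min(1, len(t) - 1)])


# ---------------------------------------------------------------------------
# Nernst equilibrium potential
# ---------------------------------------------------------------------------


def nernst_potential(c: NernstConditions) -> float:
    """K+ equilibrium potential (mV): (R*T/F) * ln([K]out/[K]in)."""
    return 1000.0 * R_GAS * c.temperature / FARADAY * math.log(c.k_out / c.k_in)


# ---------------------------------------------------------------------------
# Induction time course
# ---------------------------------------------------------------------------


def sigmoid_time_course(t, params: SigmoidParams):
    """Delayed sigmoid: ``y0`` for ``t <= t_del``, then a cubic-exponential
    rise toward ``y_max``."""
    tt = np.asarray(t, dtype=float)
    dt = np.clip(tt - params.t_del, 0.0, None)
    rise = (1.0 - np.exp(-dt / params.tau)) ** 3
    out = params.y0 + (params.y_max - params.y0) * rise
    return out if out.ndim else float(out)


def sigmoid_metrics(params: SigmoidParams) -> dict:
    """Closed-form latency metrics of the delayed sigmoid.

    ``t_q = t_del + tau * ln(1/(1 - q**(1/3)))`` for a normalized-rise
    quantile ``q``; the 20–80% rise time is ``~1.7565 * tau``.
    """
    if params.y_max == params.y0:
        raise DomainError("degenerate amplitude: y_max == y0")

    def t_q(q):
        return params.t_del + params.tau * math.log(1.0 / (1.0 - q ** (1.0 / 3.0)))

    t20, t50, t80 = t_q(0.2), t_q(0.5), t_q(0.8)
    return {"t_half": t50, "t_20": t20, "t_80": t80, "rise_20_80": t80 - t20}


def fit_sigmoid(t, y) -> FitResult:
    """Least-squares fit of the delayed sigmoid; returns params + metrics.

    Flat input (amplitude indistinguishable from residual noise) is flagged
    ``no_amplitude`` and metrics are omitted.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 8:
        raise DomainError("need >= 8 time points")

    y0_0 = float(np.mean(y[:2]))
    ymax_0 = float(np.mean(y[-3:]))
    amp = ymax_0 - y0_0
    if amp != 0:
        above = np.nonzero(y > y0_0 + 0.1 * amp)[0] if amp > 0 else \
            np.nonzero(y < y0_0 + 0.1 * amp)[0]
        td0 = float(t[above[0]]) - (t[1] - t[0]) if above.size else float(t[t.size // 2])
    else:
        td0 = float(t[t.size // 2])
    tau0 = max((t[-1] - t[0]) / 10.0, 1e-3)
    p0 = (y0_0, ymax_0, td0, tau0)

    def model(tt, y0, ymax, td, tau):
        dt = np.clip(tt - td, 0.0, None)
        return y0 + (ymax - y0) * (1.0 - np.exp(-dt / tau)) ** 3

    bounds = ([-np.inf, -np.inf, t[0] - (t[-1] - t[0]), 1e-9],
              [np.inf, np.inf, t[-1], np.inf])
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds,
                               maxfev=_MAXFEV, xtol=_XTOL, ftol=_XTOL)
    except RuntimeError as exc:
        raise FitConvergenceError(f"sigmoid fit did not converge: {exc}", p0=p0)
    params = SigmoidParams(*popt)
    resid = y - model(t, *popt)
    resid_sd = float(np.std(resid)) if t.size > 4 else 0.0
    flags = []
    extra = {"p0": p0}
    if abs(params.y_max - params.y0) <= max(3.0 * resid_sd, 1e-12):
        flags.append("no_amplitude")
    else:
        extra["metrics"] = sigmoid_metrics(params)
    return FitResult(params,
                     stderr=dict(zip(("y0", "y_max", "t_del", "tau"),
                                     np.sqrt(np.diag(pcov)))),
                     residual_norm=float(np.linalg.norm(resid)),
                     flags=flags, extra=extra)


# ---------------------------------------------------------------------------
# Canonical sensor calibrations
# ---------------------------------------------------------------------------

#: Published patch-clamp calibrations.  For rASAP the printed slope-factor
#: sign is inconsistent with the observed response directions (gramicidin
#: depolarization lowers the ratio; Kir2.1 hyperpolarization raises it), so
#: k_s is stored sign-flipped; the correction is recorded in
#: ``orientation_note``.
CALIBRATIONS = {
    "rASAP": BoltzmannParams(
        r_max=0.56,
        delta_r=-178.6,
        v_half=-11.5,
        k_s=-54.0,
        orientation_note=(
            "k_s sign inverted relative to the published fit table so the "
            "modeled ratio decreases with depolarization"
        ),
    ),
    "rArc": BoltzmannParams(
        r_max=1.0,
        delta_r=41.0,
        v_half=-49.0,
        k_s=27.8,
        orientation_note=(
            "published orientation retained; r_max normalized to 1 "
            "(absolute maximum ratio not published)"
        ),
    ),
}


def calibration_to_dict(name: str, params: BoltzmannParams, source: str = "") -> dict:
    """Serialize a calibration parameter set to a JSON-ready dict."""
    return {
        "sensor_name": name,
        "r_max": params.r_max,
        "delta_r_percent": params.delta_r,
        "v_half_mV": params.v_half,
        "k_s_mV": params.k_s,
        "source": source,
        "orientation_corrected": bool(params.orientation_note),
    }


def calibration_from_dict(d: dict) -> tuple[str, BoltzmannParams]:
    params = BoltzmannParams(
        r_max=float(d["r_max"]),
        delta_r=float(d["delta_r_percent"]),
        v_half=float(d["v_half_mV"]),
        k_s=float(d["k_s_mV"]),
        orientation_note="orientation corrected" if d.get("orientation_corrected") else "",
    )
    return str(d.get("sensor_name", "")), params
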