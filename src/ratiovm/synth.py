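"""Synthetic microscopy data with known ground truth.

Generates the data structures the analysis pipeline consumes — multi-channel
imaging fields, tabular per-cell populations, voltage-step fluorescence
traces, and induction time series — with the statistical structure the
method assumes:

* 14-bit camera counts with Poisson shot noise, Gaussian read noise, a
  camera offset, and saturation clipping;
* Hoechst-stained nuclei (disks) whose DNA-content signal is bimodal
  (a G2/M fraction at twice the G1 intensity), with optional debris and
  doublet contaminants for gating tests;
* membrane-localized green/red GEVI fluorescence in which the green channel
  follows the Boltzmann calibration of the sensor, cell-to-cell ratio
  variability is log-normal (geometric SD ~1.31 for untreated cells), and
  expression intensity is log-normal on the red channel;
* rapid, saturable photoswitching loss of the green channel across the four
  sequential green frames (the red reference is stable);
* a spatially smooth background surface per channel.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .imaging import ChannelStack
from .models import (
    CALIBRATIONS,
    BoltzmannParams,
    DomainError,
    KineticsParams,
    SigmoidParams,
    boltzmann_ratio,
    double_exp_response,
    sigmoid_time_course,
)
from .timecourse import TimecourseSeries

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "render_field",
    "simulate_population",
    "simulate_step_trace",
    "simulate_induction_series",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic imaging field.

    Geometry is in microns (``pixel_size`` um/px); intensities are expected
    camera counts before noise.  ``ratio_gsd`` is the voltage-independent
    geometric SD of the per-cell green/red ratio; ``expression_gsd`` the
    geometric SD of the red expression level.  Photoswitching multiplies the
    k-th green frame by ``(1-f) + f*exp(-(k-1)/tau)``, saturating by frame 4.
    """

    shape: tuple = (512, 512)
    pixel_size: float = 0.65
    n_cells: int = 50
    nucleus_radius_um: tuple = (4.2, 0.45)  # mean, sd (truncated normal)
    nucleus_radius_bounds_um: tuple = (3.3, 5.6)
    membrane_width_um: float = 1.5
    vm_mean: float = -40.0
    vm_sd: float = 0.0
    expression_median: float = 1200.0
    expression_gsd: float = 1.8
    ratio_gsd: float = 1.31
    calibration: BoltzmannParams = field(
        default_factory=lambda: CALIBRATIONS["rASAP"]
    )
    photoswitch_fraction: float = 0.3
    photoswitch_tau_frames: float = 0.7
    background: dict = field(
        default_factory=lambda: {"blue": 30.0, "green": 120.0, "red": 80.0}
    )
    background_rel_variation: float = 0.3
    bit_depth: int = 14
    read_noise: float = 3.0
    camera_offset: float = 100.0
    g2m_fraction: float = 0.2
    blue_g1_level: float = 1000.0
    blue_cv: float = 0.08
    debris_fraction: float = 0.0
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise DomainError("n_cells must be >= 0")
        if self.bit_depth not in (8, 12, 14, 16):
            raise DomainError("bit_depth must be one of 8, 12, 14, 16")
        for name in ("expression_gsd", "ratio_gsd"):
            if getattr(self, name) < 1.0:
                raise DomainError(f"{name} must be >= 1")
        if self.expression_median <= 0 or self.blue_g1_level <= 0:
            raise DomainError("intensity scales must be positive")


@dataclass
class GroundTruth:
    """Per-cell truth table plus the field-level background surfaces."""

    cells: pd.DataFrame
    background: dict

    def __len__(self):
        return len(self.cells)


_TRUTH_COLUMNS = [
    "row", "col", "nucleus_radius_um", "nucleus_area_um2", "vm",
    "expression", "true_ratio", "blue_level", "is_g2m", "is_debris",
    "is_doublet",
]


def photoswitch_multipliers(fraction: float, tau_frames: float, n_frames: int = 4):
    """Per-frame green multipliers: ``(1-f) + f*exp(-(k-1)/tau)``."""
    k = np.arange(n_frames, dtype=float)
    return (1.0 - fraction) + fraction * np.exp(-k / max(tau_frames, 1e-9))


def _smooth_surface(rng, shape, level, rel_variation):
    """Spatially smooth positive background around ``level`` counts."""
    coarse = rng.standard_normal((4, 4))
    zoom = (shape[0] / 4.0, shape[1] / 4.0)
    surf = ndi.zoom(coarse, zoom, order=3, mode="nearest")[: shape[0], : shape[1]]
    peak = np.abs(surf).max()
    if peak > 0:
        surf = surf / peak
    return np.clip(level * (1.0 + rel_variation * surf), 0.0, None)


def _place_cells(rng, spec: SceneSpec):
    """Jittered-grid cell centers keeping nuclei separated and off the edge."""
    r_cell_um = spec.nucleus_radius_bounds_um[1] + spec.membrane_width_um
    margin = int(math.ceil(r_cell_um / spec.pixel_size)) + 2
    pitch = int(math.ceil(2.0 * r_cell_um / spec.pixel_size)) + 2
    rows = np.arange(margin + pitch // 2, spec.shape[0] - margin, pitch)
    cols = np.arange(margin + pitch // 2, spec.shape[1] - margin, pitch)
    sites = [(r, c) for r in rows for c in cols]
    if spec.n_cells > len(sites):
        raise DomainError(
            f"cell count {spec.n_cells} infeasible for field {spec.shape} "
            f"(capacity {len(sites)})"
        )
    chosen = rng.choice(len(sites), size=spec.n_cells, replace=False)
    jitter = pitch * 0.1
    centers = []
    for idx in chosen:
        r, c = sites[idx]
        centers.append(
            (r + rng.uniform(-jitter, jitter), c + rng.uniform(-jitter, jitter))
        )
    return centers


def _sample_cells(rng, spec: SceneSpec, n: int) -> pd.DataFrame:
    mu_r, sd_r = spec.nucleus_radius_um
    radii = np.clip(rng.normal(mu_r, sd_r, n), *spec.nucleus_radius_bounds_um)
    vm = rng.normal(spec.vm_mean, spec.vm_sd, n) if spec.vm_sd > 0 else np.full(n, spec.vm_mean)
    expression = spec.expression_median * np.exp(
        rng.normal(0.0, math.log(spec.expression_gsd), n)
    )
    ratio = boltzmann_ratio(vm, spec.calibration) * np.exp(
        rng.normal(0.0, math.log(spec.ratio_gsd), n)
    )
    is_g2m = rng.random(n) < spec.g2m_fraction
    blue = spec.blue_g1_level * np.where(is_g2m, 2.0, 1.0)
    blue = blue * (1.0 + spec.blue_cv * rng.standard_normal(n))
    u = rng.random(n)
    is_debris = u < spec.debris_fraction
    is_doublet = (~is_debris) & (u < spec.debris_fraction + spec.doublet_fraction)
    blue = np.where(is_debris, 0.3 * blue, blue)
    blue = np.where(is_doublet, 4.0 * blue, blue)
    return pd.DataFrame(
        {
            "nucleus_radius_um": radii,
            "nucleus_area_um2": math.pi * radii**2,
            "vm": vm,
            "expression": expression,
            "true_ratio": ratio,
            "blue_level": np.clip(blue, 1.0, None),
            "is_g2m": is_g2m,
            "is_debris": is_debris,
            "is_doublet": is_doublet,
        }
    )


def render_field(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Cells are disks: the nucleus carries the blue DNA signal; green and red
    fluorescence cover the whole cell footprint (nucleus plus a membrane
    annulus) so that the mean green/red over the nuclear ROI equals the
    cell's true ratio (times the photoswitch multiplier of the measured
    frame).  Camera model: Poisson shot noise + Gaussian read noise +
    offset, clipped to the bit-depth ceiling.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    ceiling = float(2**spec.bit_depth - 1)

    centers = _place_cells(rng, spec) if spec.n_cells else []
    cells = _sample_cells(rng, spec, spec.n_cells)
    cells.insert(0, "col", [c for _, c in centers] if centers else [])
    cells.insert(0, "row", [r for r, _ in centers] if centers else [])

    blue = np.zeros((h, w))
    red = np.zeros((h, w))
    green_base = np.zeros((h, w))
    for rec in cells.itertuples():
        r_nuc_px = rec.nucleus_radius_um / spec.pixel_size
        r_cell_px = (rec.nucleus_radius_um + spec.membrane_width_um) / spec.pixel_size
        rr, cc = draw_disk((rec.row, rec.col), r_cell_px, shape=(h, w))
        red[rr, cc] += rec.expression
        green_base[rr, cc] += rec.expression * rec.true_ratio
        rr, cc = draw_disk((rec.row, rec.col), r_nuc_px, shape=(h, w))
        blue[rr, cc] += rec.blue_level

    backgrounds = {
        ch: _smooth_surface(rng, (h, w), level, spec.background_rel_variation)
        for ch, level in spec.background.items()
    }

    def camera(expected):
        img = rng.poisson(np.clip(expected, 0.0, None)).astype(float)
        img += rng.normal(0.0, spec.read_noise, expected.shape)
        img += spec.camera_offset
        return np.clip(img, 0.0, ceiling)

    mult = photoswitch_multipliers(
        spec.photoswitch_fraction, spec.photoswitch_tau_frames, 4
    )
    blue_img = camera(blue + backgrounds["blue"])
    green_imgs = [camera(m * green_base + backgrounds["green"]) for m in mult]
    red_img = camera(red + backgrounds["red"])

    stack = ChannelStack(
        blue=blue_img,
        green=green_imgs,
        red=red_img,
        pixel_size=spec.pixel_size,
        bit_depth=spec.bit_depth,
        camera_offset={
            "blue": spec.camera_offset,
            "green": spec.camera_offset,
            "red": spec.camera_offset,
        },
    )
    truth = GroundTruth(cells=cells[_TRUTH_COLUMNS] if len(cells) else
                        pd.DataFrame(columns=_TRUTH_COLUMNS),
                        background=backgrounds)
    return stack, truth


def simulate_population(
    n: int,
    vm,
    expression_gsd: float = 1.8,
    ratio_gsd: float = 1.31,
    calibration: BoltzmannParams | None = None,
    expression_median: float = 1200.0,
    g2m_fraction: float = 0.2,
    blue_g1_level: float = 1000.0,
    blue_cv: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabular per-cell population bypassing image rendering.

    ``vm`` may be a scalar or an array of length ``n``.  Returns a frame
    with columns ``f_red`` (log-normal expression), ``f_green`` (red times
    the Boltzmann ratio times log-normal ratio noise of geometric SD
    ``ratio_gsd``), ``f_blue``, ``vm`` and ``saturated`` (always False).
    """
    if n <= 0:
        raise DomainError("n must be > 0")
    if ratio_gsd < 1.0 or expression_gsd < 1.0:
        raise DomainError("geometric SDs must be >= 1")
    calibration = calibration or CALIBRATIONS["rASAP"]
    rng = np.random.default_rng(seed)
    vm_arr = np.broadcast_to(np.asarray(vm, dtype=float), (n,)).copy()
    f_red = expression_median * np.exp(rng.normal(0, math.log(expression_gsd), n))
    ratio = boltzmann_ratio(vm_arr, calibration) * np.exp(
        rng.normal(0, math.log(ratio_gsd), n)
    )
    is_g2m = rng.random(n) < g2m_fraction
    f_blue = blue_g1_level * np.where(is_g2m, 2.0, 1.0) * (
        1.0 + blue_cv * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {
            "f_red": f_red,
            "f_green": f_red * ratio,
            "f_blue": f_blue,
            "vm": vm_arr,
            "saturated": False,
        }
    )


def simulate_step_trace(
    params: KineticsParams,
    duration_ms: float = 500.0,
    rate_hz: float = 20000.0,
    noise_sd: float = 0.01,
    seed: int = 0,
):
    """Voltage-step fluorescence trace on a uniform sampling grid.

    Returns ``(t_ms, f)``; ``noise_sd`` is additive Gaussian noise on the
    normalized fluorescence.
    """
    if duration_ms <= 0:
        raise DomainError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, 1000.0 / rate_hz)
    f = double_exp_response(t, params)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, t.shape)
    return t, f


def simulate_induction_series(
    params: SigmoidParams,
    sampling_min: float = 10.0,
    duration_min: float = 240.0,
    transient_amplitude: float = 0.0,
    transient_tau_min: float | None = None,
    noise_sd: float = 0.0,
    t_start: float = -30.0,
    seed: int = 0,
    label: str = "",
) -> TimecourseSeries:
    """Slow induction time series sampled every ``sampling_min`` minutes.

    The optional handling transient — a brief ratio bump right after
    solution application that decays over about two sampling intervals — is
    applied multiplicatively to all post-application samples so that it
    cancels when an induced series is normalized to a control sharing it.
    """
    if duration_min < params.t_del + 5.0 * params.tau:
        raise DomainError("duration must cover t_del + 5*tau")
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, duration_min + sampling_min / 2.0, sampling_min)
    y = np.asarray(sigmoid_time_course(t, params), dtype=float)
    if transient_amplitude:
        tau_tr = transient_tau_min if transient_tau_min is not None else sampling_min
        post = t >= 0
        y = np.where(post, y * (1.0 + transient_amplitude * np.exp(-t / tau_tr)), y)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, t.shape)
    return TimecourseSeries(t=t, mean=y, sem=np.full(t.shape, noise_sd), label=label)
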