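"""Per-field image processing for high-content ratiometric imaging.

One imaging field consists of a blue nuclear (Hoechst) frame, four
sequential green GEVI frames, and one red reference frame.  Processing
follows the standard high-content recipe: camera-offset and rolling-ball
background subtraction, nuclear segmentation on the blue channel
(threshold -> watershed -> particle analysis with size and edge filters),
and per-nucleus mean-intensity extraction.  Only the fourth green frame is
quantified, after the rapid photoswitching loss of the green fluorophore has
saturated.

For long-term time-lapse data (no nuclear stain), a red-intensity mask
replaces segmentation (:func:`masked_timelapse_extract`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import restoration, transform
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .models import DomainError

__all__ = [
    "ChannelStack",
    "CELL_COLUMNS",
    "subtract_background",
    "subtract_background_stack",
    "segment_nuclei",
    "extract_cells",
    "masked_timelapse_extract",
]

#: Stable column names of the per-cell record table.
CELL_COLUMNS = [
    "roi_id",
    "row",
    "col",
    "area_um2",
    "f_blue",
    "f_green",
    "f_red",
    "touches_edge",
    "saturated",
]

_VALID_BIT_DEPTHS = (8, 12, 14, 16)


@dataclass
class ChannelStack:
    """One multi-channel imaging field.

    ``green`` is an ordered list of frames (4 in high-content mode).
    ``camera_offset`` maps channel name -> offset counts.  After background
    subtraction (``background_subtracted=True``) pixel values may be small
    negatives; ``saturation_mask`` marks pixels that were at the bit-depth
    ceiling in the raw green (frame used for analysis) or red frames.
    """

    blue: np.ndarray
    green: list
    red: np.ndarray
    transmission: np.ndarray | None = None
    pixel_size: float = 0.65
    bit_depth: int = 14
    camera_offset: dict = field(
        default_factory=lambda: {"blue": 0.0, "green": 0.0, "red": 0.0}
    )
    background_subtracted: bool = False
    saturation_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.bit_depth not in _VALID_BIT_DEPTHS:
            raise DomainError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}")
        shapes = {np.shape(self.blue), np.shape(self.red)}
        shapes.update(np.shape(g) for g in self.green)
        if self.transmission is not None:
            shapes.add(np.shape(self.transmission))
        if len(shapes) != 1:
            raise DomainError("all channel frames must share one shape")
        if len(self.green) < 1:
            raise DomainError("need at least one green frame")

    @property
    def ceiling(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def analysis_green(self) -> np.ndarray:
        """Green frame used for quantification: the fourth when available."""
        return self.green[3] if len(self.green) >= 4 else self.green[-1]


def subtract_background(
    image: np.ndarray,
    ball_radius_um: float,
    pixel_size: float,
    camera_offset: float = 0.0,
) -> np.ndarray:
    """Camera-offset plus rolling-ball background subtraction.

    The rolling-ball estimate (morphological background with a spherical
    structuring element) is computed on a lightly smoothed copy so the ball
    rides on the noise mean rather than its lower envelope; for large balls
    the image is downscaled first and the background resized back, which
    approximates the full-resolution estimate at a fraction of the cost.
    Output is float and not clipped: small negatives are retained so that
    downstream ratio statistics stay unbiased.
    """
    radius_px = ball_radius_um / pixel_size
    if radius_px < 2:
        raise DomainError(
            f"ball radius {ball_radius_um} um is {radius_px:.2f} px at "
            f"{pixel_size} um/px; need >= 2 px"
        )
    img = np.asarray(image, dtype=float) - camera_offset
    if radius_px > 32:
        factor = int(math.ceil(radius_px / 32.0))
        small_shape = tuple(max(s // factor, 8) for s in img.shape)
        small = transform.resize(img, small_shape, anti_aliasing=True)
        bg_small = restoration.rolling_ball(small, radius=radius_px / factor)
        bg = transform.resize(bg_small, img.shape)
    else:
        bg = restoration.rolling_ball(gaussian(img, sigma=1, preserve_range=True),
                                      radius=radius_px)
    return img - bg


def subtract_background_stack(
    stack: ChannelStack, ball_radius_um: float = 146.0
) -> ChannelStack:
    """Background-subtract every channel of a field.

    Also computes the saturation mask (analysis green or red at the raw
    bit-depth ceiling) before subtraction.
    """
    if stack.background_subtracted:
        return stack
    sat = (np.asarray(stack.analysis_green) >= stack.ceiling) | (
        np.asarray(stack.red) >= stack.ceiling
    )
    off = stack.camera_offset

    def sub(img, channel):
        return subtract_background(
            img, ball_radius_um, stack.pixel_size, off.get(channel, 0.0)
        )

    return replace(
        stack,
        blue=sub(stack.blue, "blue"),
        green=[sub(g, "green") for g in stack.green],
        red=sub(stack.red, "red"),
        transmission=(
            sub(stack.transmission, "transmission")
            if stack.transmission is not None
            else None
        ),
        background_subtracted=True,
        saturation_mask=sat,
    )


def segment_nuclei(
    blue: np.ndarray,
    pixel_size: float,
    threshold="auto",
    area_min_um2: float = 26.0,
    area_max_um2: float = 117.0,
) -> np.ndarray:
    """Nuclear segmentation of a background-subtracted blue frame.

    Threshold (Otsu when ``"auto"``) -> binary mask -> distance-transform
    watershed to split touching nuclei -> particle analysis.  Particles
    touching the image edge and particles outside ``[area_min, area_max]``
    um^2 (inclusive bounds) are removed.  Returns a label image with
    retained nuclei labeled 1..n (0 = background); an empty mask yields an
    all-zero label image.
    """
    img = np.asarray(blue, dtype=float)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise DomainError(f"unknown threshold mode {threshold!r}")
        if np.ptp(img) == 0:
            raise DomainError("constant image: automatic threshold unavailable")
        # Otsu, but never below the background noise floor: on a field with
        # no nuclei Otsu merely splits the noise distribution
        mad = np.median(np.abs(img - np.median(img)))
        noise_floor = float(np.median(img) + 6.0 * 1.4826 * mad)
        thr = max(float(threshold_otsu(img)), noise_floor)
    else:
        thr = float(threshold)
        if thr <= 0:
            raise DomainError("explicit threshold must be positive counts")
    mask = img > thr
    labels = np.zeros(img.shape, dtype=np.int32)
    if not mask.any():
        return labels

    distance = ndi.distance_transform_edt(mask)
    # seed separation: radius of the smallest acceptable nucleus
    min_dist = max(2, int(round(math.sqrt(area_min_um2 / math.pi) / pixel_size)))
    coords = peak_local_max(distance, min_distance=min_dist, labels=mask,
                            exclude_border=False)
    seeds = np.zeros(mask.shape, dtype=bool)
    seeds[tuple(coords.T)] = True
    markers, _ = ndi.label(seeds)
    ws = watershed(-distance, markers, mask=mask)

    h, w = img.shape
    next_label = 1
    for region_label in range(1, int(ws.max()) + 1):
        region = ws == region_label
        if not region.any():
            continue
        rows, cols = np.nonzero(region)
        if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
            continue  # particle crosses the field edge
        area_um2 = rows.size * pixel_size**2
        if area_um2 < area_min_um2 or area_um2 > area_max_um2:
            continue
        labels[region] = next_label
        next_label += 1
    return labels


def extract_cells(stack: ChannelStack, labels: np.ndarray) -> pd.DataFrame:
    """Per-nucleus mean fluorescence in blue, red, and the analysis green.

    Requires a background-subtracted stack.  ``saturated`` marks nuclei
    containing any raw green/red pixel at the bit-depth ceiling.
    """
    if not stack.background_subtracted:
        raise DomainError("stack must be background-subtracted before extraction")
    labels = np.asarray(labels)
    if labels.shape != np.shape(stack.blue):
        raise DomainError("label image shape does not match the field")
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=CELL_COLUMNS)
    index = np.arange(1, n + 1)
    area_px = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, index)
    com = ndi.center_of_mass(np.ones_like(labels, dtype=float), labels, index)
    mean_blue = ndi.mean(np.asarray(stack.blue, dtype=float), labels, index)
    mean_green = ndi.mean(np.asarray(stack.analysis_green, dtype=float), labels, index)
    mean_red = ndi.mean(np.asarray(stack.red, dtype=float), labels, index)
    if stack.saturation_mask is not None:
        sat = ndi.maximum(stack.saturation_mask.astype(float), labels, index) > 0
    else:
        sat = np.zeros(n, dtype=bool)
    rows = np.array([c[0] for c in com])
    cols = np.array([c[1] for c in com])
    return pd.DataFrame(
        {
            "roi_id": index,
            "row": rows,
            "col": cols,
            "area_um2": area_px * stack.pixel_size**2,
            "f_blue": mean_blue,
            "f_green": mean_green,
            "f_red": mean_red,
            "touches_edge": False,
            "saturated": sat,
        }
    )


def masked_timelapse_extract(
    green: np.ndarray,
    red: np.ndarray,
    red_lo: float = 500.0,
    red_hi: float = 3500.0,
) -> tuple[float, int]:
    """Red-intensity-masked mean ratio for time-lapse frames.

    Pixels with red strictly inside ``(red_lo, red_hi)`` form the mask; the
    returned ratio is mean(green over mask) / mean(red over mask).  An empty
    mask returns ``(nan, 0)`` rather than raising.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    mask = (red > red_lo) & (red < red_hi)
    n = int(mask.sum())
    if n == 0:
        return (float("nan"), 0)
    return (float(green[mask].mean() / red[mask].mean()), n)
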