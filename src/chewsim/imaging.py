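"""Bolus-image ROI extraction and the pixel-variance homogeneity statistic.

A surface-coloured cheese mixes its coloured and white phases as it is
chewed, so the spatial variance of pixel intensities inside the bolus region
is a homogeneity index: the higher the variance, the less mixed the bolus.
Photographs are taken on a green background; the region of interest (ROI) is
recovered by chroma-keying the background out, keeping the largest connected
foreground component, and optionally eroding the boundary to trim shadow
fringes.

Intensities are handled on a normalised [0, 1] scale (8-bit values divided
by 255); variances are population variances (divide by N) of the chosen
channel restricted to the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np
from skimage import color as skcolor
from skimage import measure, morphology

from . import stats as _stats

__all__ = [
    "CHANNELS",
    "ChromaKeySpec",
    "InVivoOrigin",
    "InVitroOrigin",
    "BolusImage",
    "HomogeneityScore",
    "EmptyROIError",
    "extract_roi",
    "channel_variance",
    "select_channel",
]

Channel = Literal["red", "green", "blue"]

#: Channel order; also the tie-break priority for channel selection.
CHANNELS: tuple[Channel, ...] = ("red", "green", "blue")
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

STAGES = (33, 66, 99)


class EmptyROIError(ValueError):
    """Raised when background removal leaves no foreground pixel."""


@dataclass(frozen=True)
class InVivoOrigin:
    subject_id: str
    group: str  # "child" or "adult"
    stage: int  # % of individual mastication time

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage}")


@dataclass(frozen=True)
class InVitroOrigin:
    n_compressions: int
    rotation_speed: float  # rpm


Origin = Union[InVivoOrigin, InVitroOrigin]


@dataclass(frozen=True)
class ChromaKeySpec:
    """Background description for chroma-key segmentation.

    hue is on the [0, 1) HSV circle (pure green ≈ 1/3).  A pixel is
    classified as background when its circular hue distance to `hue` is at
    most `tolerance` and its saturation is at least `min_saturation` (the
    saturation floor keeps near-grey foreground pixels, whose hue is
    meaningless, out of the key).  After keying, the foreground boundary is
    eroded by `erosion_radius` pixels to trim shadow fringes.
    """

    hue: float = 1.0 / 3.0
    tolerance: float = 0.10
    min_saturation: float = 0.15
    erosion_radius: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue < 1.0:
            raise ValueError("hue must lie in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.erosion_radius < 0:
            raise ValueError("erosion_radius must be >= 0")


@dataclass
class BolusImage:
    """An RGB bolus photograph with its region of interest.

    pixels: (H, W, 3) float array of intensities in [0, 1], row-major,
    origin top-left.  roi: (H, W) boolean mask, True inside the bolus.
    """

    pixels: np.ndarray
    roi: np.ndarray
    origin: Origin
    replicate: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.roi.shape != self.pixels.shape[:2]:
            raise ValueError("roi shape must match pixel grid")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def n_roi_pixels(self) -> int:
        return int(self.roi.sum())


@dataclass(frozen=True)
class HomogeneityScore:
    """Population variance of one channel's intensities inside the ROI."""

    channel: Channel
    variance: float
    origin: Origin
    replicate: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance <= 0.25 + 1e-12:
            raise ValueError(
                "variance on the normalised scale must lie in [0, 0.25], "
                f"got {self.variance}"
            )


def _as_float_rgb(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw)
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {raw.shape}")
    raw = raw[:, :, :3]
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / 255.0
    out = raw.astype(float)
    if out.max() > 1.0:  # float image still on the 0..255 scale
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def extract_roi(
    raw: np.ndarray,
    background: ChromaKeySpec = ChromaKeySpec(),
    *,
    origin: Origin | None = None,
    replicate: int = 1,
) -> BolusImage:
    """Chroma-key the background away and keep the largest foreground blob.

    Parameters
    ----------
    raw : (H, W, 3) array
        RGB image, uint8 or float.
    background : ChromaKeySpec
        Background hue, tolerance, saturation floor and erosion radius.

    Returns
    -------
    BolusImage with roi = largest connected non-background component,
    eroded by ``background.erosion_radius``.

    Raises
    ------
    EmptyROIError
        If every pixel is classified as background (or erosion removes the
        whole component).
    """
    pixels = _as_float_rgb(raw)
    hsv = skcolor.rgb2hsv(pixels)
    hue_dist = np.abs(hsv[:, :, 0] - background.hue)
    hue_dist = np.minimum(hue_dist, 1.0 - hue_dist)  # circular distance
    is_background = (hue_dist <= background.tolerance) & (
        hsv[:, :, 1] >= background.min_saturation
    )
    foreground = ~is_background
    if not foreground.any():
        raise EmptyROIError("all pixels classified as background")

    labels = measure.label(foreground, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    roi = labels == counts.argmax()

    if background.erosion_radius > 0:
        roi = morphology.erosion(
            roi, morphology.disk(background.erosion_radius)
        ).astype(bool)
        if not roi.any():
            raise EmptyROIError("erosion removed the whole foreground component")

    if origin is None:
        origin = InVitroOrigin(n_compressions=1, rotation_speed=4.0)
    return BolusImage(pixels=pixels, roi=roi, origin=origin, replicate=replicate)


def channel_variance(image: BolusImage, channel: Channel = "red") -> HomogeneityScore:
    """Population variance of one colour channel inside the ROI."""
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"unknown channel {channel!r}")
    if image.n_roi_pixels == 0:
        raise EmptyROIError("cannot compute variance on an empty ROI")
    values = image.pixels[:, :, _CHANNEL_INDEX[channel]][image.roi]
    var = float(np.var(values))  # population (divide by N)
    return HomogeneityScore(
        channel=channel,
        variance=min(var, 0.25),
        origin=image.origin,
        replicate=image.replicate,
    )


def select_channel(
    images: Sequence[BolusImage], group_labels: Sequence[str]
) -> Channel:
    """Pick the channel whose per-image variances best separate the groups.

    For each channel, the per-image ROI variances are scored with a one-way
    between-group ANOVA; the channel with the largest F statistic wins.
    Ties (including the all-degenerate F = +inf case) are broken in the
    fixed priority red > green > blue.
    """
    if len(images) != len(group_labels):
        raise ValueError("images and group_labels must have equal length")
    groups = sorted(set(group_labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups to select a channel")
    for g in groups:
        if sum(1 for lbl in group_labels if lbl == g) < 2:
            raise ValueError(f"group {g!r} needs at least two images")

    best: Channel = CHANNELS[0]
    best_f = -np.inf
    for chan in CHANNELS:
        variances = [channel_variance(img, chan).variance for img in images]
        f = _stats.one_way_anova(variances, group_labels).F
        if f > best_f:  # strict: earlier (red-first) channel wins ties
            best, best_f = chan, f
    return best
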