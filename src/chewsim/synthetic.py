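"""Synthetic study data: panels, two-phase mixing images, force curves.

The raw study data (subject tables, bolus photographs, force curves) are not
public, so every pipeline input can be regenerated here with the statistical
structure the analysis assumes:

* panels — per-subject masticatory parameters drawn from truncated-at-zero
  normals whose means/SDs default to the published child and adult group
  summaries;
* bolus images — a disk-shaped bolus on a green background whose coloured
  surface layer (an annular sector of exact area fraction f) is mixed by a
  differential-rotation shear (the stirring plunger) followed by a Gaussian
  fold blur; red-channel variance then decreases with compressions and with
  rotation speed, like real boli;
* force curves — saturating ramps whose endpoint is the target hardness;
* triangle-test sessions — Bernoulli panels with a discriminator fraction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import datasets
from .imaging import BolusImage, InVitroOrigin, InVivoOrigin
from .invivo import PanelistRecord
from .texture import ForceCurve

__all__ = [
    "PanelSpec",
    "MixSpec",
    "generate_panel",
    "generate_bolus_image",
    "generate_invivo_image_set",
    "generate_invitro_image_set",
    "generate_force_curve",
    "invitro_hardness_mean",
    "generate_triangle_session",
    "CHILD_MIX",
    "ADULT_MIX",
]

# variables a PanelSpec draws per subject
_PANEL_VARS = (
    "mouth_volume",
    "quantity_consumed",
    "mastication_time",
    "n_compressions",
    "saliva_volume",
)


def _default_group_params(group: str) -> dict[str, tuple[float, float]]:
    summary = datasets.PANEL_SUMMARY[group]
    return {v: summary[v] for v in _PANEL_VARS}


@dataclass(frozen=True)
class PanelSpec:
    """Generating (mean, SD) per parameter for one group of subjects."""

    group: str
    size: int = 30
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    replicate_cv: float = 0.03  # within-subject triplicate noise, rel. SD

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("panel size must be >= 1")
        merged = _default_group_params(self.group)
        merged.update(self.params)
        for name, (mu, sd) in merged.items():
            if sd < 0:
                raise ValueError(f"{name}: SD must be nonnegative")
        object.__setattr__(self, "params", merged)


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int, floor: float = 0.0
) -> np.ndarray:
    """Rejection sampling of N(mu, sd) truncated below at `floor`."""
    if sd == 0:
        return np.full(size, float(mu))
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mu, sd, remaining.size)
        ok = draw > floor
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_panel(spec: PanelSpec, seed: int | np.random.Generator = 0) -> list[PanelistRecord]:
    """Draw one panel of subjects from a PanelSpec.

    Each parameter is drawn once per subject from a truncated-at-zero
    normal, then measured in triplicate with small multiplicative noise
    (relative SD ``replicate_cv``); the record holds the triplicate means,
    with the raw triplicates kept in ``meta['replicates']``.  Compression
    counts are rounded to integers with a floor of 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = {
        name: _truncated_normal(rng, mu, sd, spec.size)
        for name, (mu, sd) in spec.params.items()
    }
    records = []
    for i in range(spec.size):
        reps = {
            name: draws[name][i]
            * np.maximum(1.0 + rng.normal(0.0, spec.replicate_cv, 3), 1e-6)
            for name in draws
        }
        mean = {name: float(r.mean()) for name, r in reps.items()}
        records.append(
            PanelistRecord(
                id=f"{spec.group}-{i + 1:02d}",
                group=spec.group,
                mouth_volume=mean["mouth_volume"],
                quantity_consumed=mean["quantity_consumed"],
                mastication_time=mean["mastication_time"],
                n_compressions=max(1, round(mean["n_compressions"])),
                saliva_volume_measured=mean["saliva_volume"],
                meta={"replicates": {k: v.tolist() for k, v in reps.items()}},
            )
        )
    return records


# ---------------------------------------------------------------------------
# two-phase mixing images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixSpec:
    """Forward model of coloured-surface bolus mixing.

    The initial bolus is a disk (radius_frac x image size) whose coloured
    surface layer is an annular sector of exact pixel-area fraction
    ``colored_fraction`` over a white core.  One run applies a differential
    rotation of total twist angle shear_rate x rpm x n_compressions (zero at
    the rim, maximal at the centre) followed by a fold blur of scale
    sigma_c x sqrt(n_compressions), then additive Gaussian pixel noise.
    """

    shape: tuple[int, int] = (128, 128)
    colored_fraction: float = 0.30
    colored_rgb: tuple[float, float, float] = (0.55, 0.25, 0.50)  # purple
    base_rgb: tuple[float, float, float] = (0.93, 0.90, 0.85)  # white cheese
    background_rgb: tuple[float, float, float] = (0.20, 0.70, 0.25)  # green
    radius_frac: float = 0.42
    inner_radius_frac: float = 0.45  # of the disk radius; annulus inner edge
    sigma_c: float = 2.0  # fold blur scale per compression, px
    shear_rate: float = 0.05  # rad per rpm per compression
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.colored_fraction < 1.0:
            raise ValueError("colored_fraction must lie in (0, 1)")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("colored_rgb", "base_rgb", "background_rgb"):
            if any(not 0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ValueError(f"{name} components must lie in [0, 1]")
        sector = self.colored_fraction / (1.0 - self.inner_radius_frac**2)
        if sector >= 1.0:
            raise ValueError(
                "colored_fraction too large for the annulus geometry "
                "(reduce it or inner_radius_frac)"
            )


#: Child boli mix less efficiently (fewer teeth, smaller tongue work): a
#: smaller fold scale than adults reproduces the higher child variances.
CHILD_MIX = MixSpec(sigma_c=1.2)
ADULT_MIX = MixSpec(sigma_c=2.0)


def _initial_phase_mask(spec: MixSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disk ROI mask and coloured-phase mask (exact area fraction)."""
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.radius_frac * min(h, w)
    r = np.hypot(yy - cy, xx - cx)
    roi = r <= radius
    theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)

    sector_frac = spec.colored_fraction / (1.0 - spec.inner_radius_frac**2)
    colored = roi & (r >= spec.inner_radius_frac * radius) & (
        theta < 2 * np.pi * sector_frac
    )
    # trim/grow to the exact pixel count so the two-point variance formula
    # holds with colored_fraction itself
    target = int(round(spec.colored_fraction * roi.sum()))
    current = int(colored.sum())
    if current > target:
        idx = np.flatnonzero(colored.ravel())[: current - target]
        colored.ravel()[idx] = False
    elif current < target:
        candidates = roi & ~colored
        idx = np.flatnonzero(candidates.ravel())[: target - current]
        colored.ravel()[idx] = True
    return roi, colored


def _masked_blur(channel: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur confined to the mask (normalised convolution)."""
    m = mask.astype(float)
    num = ndimage.gaussian_filter(channel * m, sigma)
    den = ndimage.gaussian_filter(m, sigma)
    out = channel.copy()
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def _differential_rotation(
    img: np.ndarray, roi: np.ndarray, total_angle: float, radius: float
) -> np.ndarray:
    """Rotate ROI content by an angle decreasing linearly from centre to rim."""
    h, w = roi.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    ang = total_angle * np.clip(1.0 - r / radius, 0.0, 1.0)
    cos_a, sin_a = np.cos(-ang), np.sin(-ang)  # inverse map
    src_y = cy + dy * cos_a - dx * sin_a
    src_x = cx + dy * sin_a + dx * cos_a
    out = img.copy()
    for c in range(img.shape[2]):
        warped = ndimage.map_coordinates(
            img[:, :, c], [src_y, src_x], order=1, mode="nearest"
        )
        out[:, :, c][roi] = warped[roi]
    return out


def generate_bolus_image(
    spec: MixSpec,
    n_compressions: int,
    rotation_speed: float,
    seed: int | np.random.Generator = 0,
    *,
    origin=None,
    replicate: int = 1,
) -> BolusImage:
    """Forward-simulate one bolus photograph at a given mixing intensity."""
    if n_compressions < 0:
        raise ValueError("n_compressions must be >= 0")
    if rotation_speed < 0:
        raise ValueError("rotation_speed must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    roi, colored = _initial_phase_mask(spec)
    h, w = spec.shape
    img = np.empty((h, w, 3))
    img[:] = spec.background_rgb
    img[roi] = spec.base_rgb
    img[colored] = spec.colored_rgb

    if n_compressions > 0:
        radius = spec.radius_frac * min(h, w)
        twist = spec.shear_rate * rotation_speed * n_compressions
        if twist > 0:
            img = _differential_rotation(img, roi, twist, radius)
        sigma = spec.sigma_c * math.sqrt(n_compressions)
        for c in range(3):
            img[:, :, c] = _masked_blur(img[:, :, c], roi, sigma)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    if origin is None:
        origin = InVitroOrigin(
            n_compressions=max(1, n_compressions),
            rotation_speed=max(rotation_speed, 1e-9),
        )
    return BolusImage(
        pixels=img,
        roi=roi,
        origin=origin,
        replicate=replicate,
        meta={"colored_fraction": float(colored.sum() / roi.sum()),
              "n_compressions": n_compressions,
              "rotation_speed": rotation_speed},
    )


def generate_invivo_image_set(
    panel: Sequence[PanelistRecord],
    child_mix: MixSpec = CHILD_MIX,
    adult_mix: MixSpec = ADULT_MIX,
    seed: int | np.random.Generator = 0,
    *,
    stages: Sequence[int] = (33, 66, 99),
    replicates: int = 2,
    rotation_speed: float = 8.0,
) -> list[BolusImage]:
    """Bolus images for every subject x stage x replicate.

    The mixing intensity at a stage is the subject's compression count
    scaled by the stage fraction (compressions accumulate roughly uniformly
    in time), rounded, floor 0.  ``rotation_speed`` is the nominal in-mouth
    stirring equivalent shared by all subjects.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    specs = {"child": child_mix, "adult": adult_mix}
    images = []
    for rec in panel:
        for stage in stages:
            eff = max(0, round(stage / 100.0 * rec.n_compressions))
            for rep in range(1, replicates + 1):
                images.append(
                    generate_bolus_image(
                        specs[rec.group],
                        eff,
                        rotation_speed,
                        rng,
                        origin=InVivoOrigin(
                            subject_id=rec.id, group=rec.group, stage=stage
                        ),
                        replicate=rep,
                    )
                )
    return images


def generate_invitro_image_set(
    settings,
    spec: MixSpec = ADULT_MIX,
    seed: int | np.random.Generator = 0,
    *,
    replicates: int = 2,
) -> list[BolusImage]:
    """Bolus images for every masticator setting x replicate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    images = []
    for s in settings:
        for rep in range(1, replicates + 1):
            images.append(
                generate_bolus_image(
                    spec,
                    s.n_compressions,
                    s.rotation_speed,
                    rng,
                    origin=InVitroOrigin(
                        n_compressions=s.n_compressions,
                        rotation_speed=s.rotation_speed,
                    ),
                    replicate=rep,
                )
            )
    return images


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def generate_force_curve(
    true_hardness: float,
    mode: str = "back_extrusion",
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    n_samples: int = 200,
    travel: Optional[float] = None,
    curvature: float = 3.0,
    origin=None,
    replicate: int = 1,
) -> ForceCurve:
    """Saturating force ramp whose endpoint is exactly the target hardness.

    F(x) = H (1 - exp(-k x)) / (1 - exp(-k)) for x = d / d_max, plus
    N(0, noise_sd) per sample; at zero noise the extracted final charge
    equals ``true_hardness`` exactly.
    """
    if true_hardness < 0:
        raise ValueError("true_hardness must be nonnegative")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if travel is None:
        travel = 7.0 if mode == "penetration" else 10.0
    x = np.linspace(0.0, 1.0, n_samples)
    force = true_hardness * (1.0 - np.exp(-curvature * x)) / (1.0 - math.exp(-curvature))
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n_samples)
    return ForceCurve(
        displacement=x * travel,
        force=force,
        mode=mode,
        origin=origin,
        replicate=replicate,
        meta={"true_hardness": true_hardness},
    )


def invitro_hardness_mean(
    n_compressions: int,
    rotation_speed: float,
    *,
    h_initial: float = 120.0,
    h_floor: float = 40.0,
    rate: float = 0.08,
    speed_gain: float = 0.03,
) -> float:
    """Mean bolus hardness (N) of a masticator run.

    Exponential softening in the number of compressions, accelerated by
    rotation speed: strictly decreasing in both knobs, qualitatively
    matching observed in vitro hardness trajectories.
    """
    k = rate * n_compressions * (1.0 + speed_gain * rotation_speed)
    return h_floor + (h_initial - h_floor) * math.exp(-k)


# ---------------------------------------------------------------------------
# triangle-test sessions
# ---------------------------------------------------------------------------

def generate_triangle_session(
    n_panelists: int,
    p_discriminator: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of correct answers in one simulated triangle-test session.

    Each panelist discriminates with probability ``p_discriminator`` and
    otherwise guesses among three samples, so the per-panelist success
    probability is p + (1 - p)/3.
    """
    if not 0.0 <= p_discriminator <= 1.0:
        raise ValueError("p_discriminator must lie in [0, 1]")
    if n_panelists < 0:
        raise ValueError("n_panelists must be nonnegative")
    if n_panelists == 0:
        return 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = p_discriminator + (1.0 - p_discriminator) / 3.0
    return int(rng.binomial(n_panelists, p))
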