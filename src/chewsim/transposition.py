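"""In vivo → in vitro transposition of masticatory parameters.

The masticator is a heated 375 mL vessel whose plunger ("palate") compresses
the sample against a sintered plate ("tongue") while rotating.  The in vivo
ratios are kept: the cheese mass loaded equals container volume divided by
the panel's mouth-volume-per-consumed-quantity ratio, and the artificial
saliva added before a run grows linearly with the planned number of
tongue–palate compressions,

    saliva (mL) = in vivo saliva rate x n cheese pieces x n compressions,

so a 0.05 mL/s rate with 7 pieces gives 0.35 mL at 1 compression up to
6.30 mL at 18.  The experimental grid crosses compression counts with
plunger rotation speeds (rpm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from . import datasets

__all__ = [
    "MasticatorConfig",
    "InVitroSetting",
    "in_vitro_cheese_mass",
    "in_vitro_saliva_volume",
    "build_grid",
]


@dataclass(frozen=True)
class MasticatorConfig:
    """Fixed operating constants of the masticator."""

    container_volume: float = 375.00  # mL
    temperature: float = 36.0  # °C, +/- 1 (metadata)
    n_pieces: int = 7  # cheese cubes loaded
    piece_mass: float = 4.5  # g per cube
    palate_surface: float = 63.62  # cm², plunger cylinder (metadata)

    def __post_init__(self) -> None:
        if self.container_volume <= 0:
            raise ValueError("container_volume must be positive")
        if self.n_pieces < 1:
            raise ValueError("n_pieces must be >= 1")
        if self.piece_mass <= 0:
            raise ValueError("piece_mass must be positive")


@dataclass(frozen=True)
class InVitroSetting:
    """One masticator operating point."""

    n_compressions: int
    rotation_speed: float  # rpm
    saliva_volume: float  # mL, added before the run
    cheese_mass: float  # g, computed target mass

    def __post_init__(self) -> None:
        if self.n_compressions < 1:
            raise ValueError("n_compressions must be >= 1")
        if self.rotation_speed <= 0:
            raise ValueError("rotation_speed must be positive")
        if self.saliva_volume < 0:
            raise ValueError("saliva_volume must be nonnegative")


def in_vitro_cheese_mass(
    config: MasticatorConfig,
    ratio_mouth_per_quantity: float = datasets.POOLED_RATIO_MOUTH_PER_QUANTITY,
    *,
    loaded_mass_tolerance: float = 1.5,
) -> float:
    """Cheese mass (g) preserving the in vivo mouth-volume/quantity ratio.

    container volume / ratio, rounded to 2 decimals.  The defaults give
    375.00 / 11.47 = 32.69 g.  The mass actually loadable as whole pieces
    (n_pieces x piece_mass) may differ from this target; a warning is
    emitted when the discrepancy exceeds ``loaded_mass_tolerance`` grams.
    """
    if ratio_mouth_per_quantity <= 0:
        raise ValueError("ratio_mouth_per_quantity must be positive")
    mass = round(config.container_volume / ratio_mouth_per_quantity, 2)
    loaded = config.n_pieces * config.piece_mass
    if abs(loaded - mass) > loaded_mass_tolerance:
        warnings.warn(
            f"loaded mass {loaded:.2f} g (pieces) differs from the computed "
            f"target {mass:.2f} g by more than {loaded_mass_tolerance} g",
            stacklevel=2,
        )
    return mass


def in_vitro_saliva_volume(
    saliva_rate: float, n_pieces: int, n_compressions: int
) -> float:
    """Artificial saliva (mL) to add before a run.

    rate (mL/s) x pieces x compressions; the whole volume is introduced
    before the run starts (the schedule is a precomputed total, not a flow).
    """
    if saliva_rate < 0 or n_pieces < 0 or n_compressions < 0:
        raise ValueError("all arguments must be nonnegative")
    return saliva_rate * n_pieces * n_compressions


def build_grid(
    compressions: Sequence[int] = datasets.GRID_COMPRESSIONS,
    speeds: Sequence[float] = datasets.GRID_SPEEDS,
    config: MasticatorConfig = MasticatorConfig(),
    saliva_rate: float = datasets.POOLED_SALIVA_RATE,
    ratio_mouth_per_quantity: float = datasets.POOLED_RATIO_MOUTH_PER_QUANTITY,
) -> list[InVitroSetting]:
    """Cartesian experimental grid of masticator settings.

    Deterministic ordering: ascending compressions (major), ascending speed
    (minor).  Each setting carries its own saliva volume and the shared
    cheese mass.  The default grid is 7 compression counts x 2 speeds = 14
    settings.
    """
    if not compressions or not speeds:
        raise ValueError("compressions and speeds must be nonempty")
    if len(set(compressions)) != len(compressions) or len(set(speeds)) != len(speeds):
        raise ValueError("duplicate grid points are not allowed")
    mass = in_vitro_cheese_mass(config, ratio_mouth_per_quantity)
    return [
        InVitroSetting(
            n_compressions=int(nc),
            rotation_speed=float(rpm),
            saliva_volume=in_vitro_saliva_volume(
                saliva_rate, config.n_pieces, int(nc)
            ),
            cheese_mass=mass,
        )
        for nc in sorted(compressions)
        for rpm in sorted(speeds)
    ]
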