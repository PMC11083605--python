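"""Hardness ("final charge") extraction from force–displacement records.

Two instrument protocols are supported and kept strictly separate, since
their force scales are not comparable:

* penetration — a 3 mm cylindrical probe driven 7 mm into the intact cheese
  at 0.5 mm/s (initial-product characterisation, forces ~1 N);
* back-extrusion — a 35 mm plate flattening ~10 g of bolus in a petri dish
  at 0.2 mm/s until the sample covers the dish (bolus characterisation,
  forces ~50–110 N).

The texture endpoint is the *final charge*: the force recorded at the end of
probe travel, i.e. at the last (largest) displacement sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = ["ForceCurve", "extract_hardness", "read_force_csv"]

Mode = Literal["penetration", "back_extrusion"]

#: Default probe speeds (mm/s) per test mode.
DEFAULT_SPEEDS: dict[str, float] = {"penetration": 0.5, "back_extrusion": 0.2}


@dataclass
class ForceCurve:
    """A force–displacement record from a traction–compression device."""

    displacement: np.ndarray  # mm, strictly increasing
    force: np.ndarray  # N
    mode: Mode = "back_extrusion"
    speed: Optional[float] = None  # mm/s metadata
    origin: object = None
    replicate: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.ndim != 1 or self.force.shape != self.displacement.shape:
            raise ValueError("displacement and force must be 1-D of equal length")
        if len(self.displacement) < 2:
            raise ValueError("a force curve needs at least two samples")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if np.any(self.displacement < 0):
            raise ValueError("displacement must be nonnegative")
        if self.mode not in DEFAULT_SPEEDS:
            raise ValueError(f"unknown test mode {self.mode!r}")
        if self.speed is None:
            self.speed = DEFAULT_SPEEDS[self.mode]


def extract_hardness(
    curve: ForceCurve,
    *,
    smooth_window: int = 0,
    tare: float = 0.0,
) -> float:
    """Final charge (N): the force at the end of probe travel.

    Parameters
    ----------
    curve : ForceCurve
    smooth_window : int
        If > 1, the endpoint force is the mean of the last `smooth_window`
        samples (simple moving-average smoothing of the tail); default 0
        returns the raw final sample.
    tare : float
        Baseline force offset subtracted from the result.
    """
    if smooth_window > 1:
        window = min(smooth_window, len(curve.force))
        endpoint = float(curve.force[-window:].mean())
    else:
        endpoint = float(curve.force[-1])
    return endpoint - tare


def read_force_csv(
    path: str | Path,
    mode: Mode = "back_extrusion",
    *,
    decimal_comma: bool = False,
    **curve_kwargs,
) -> ForceCurve:
    """Read a two-column ``displacement_mm,force_N`` CSV export."""
    df = pd.read_csv(path, decimal="," if decimal_comma else ".")
    missing = {"displacement_mm", "force_N"} - set(df.columns)
    if missing:
        raise ValueError(f"force CSV lacks column(s): {sorted(missing)}")
    return ForceCurve(
        displacement=df["displacement_mm"].to_numpy(),
        force=df["force_N"].to_numpy(),
        mode=mode,
        **curve_kwargs,
    )
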