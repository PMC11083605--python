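"""Per-subject masticatory parameters, derived quantities and panel summaries.

Five parameters influencing mastication are measured per subject: mouth
volume (mL), quantity naturally consumed (g), mastication time (s), number
of tongue–palate compressions, and saliva volume (mL).  Saliva is inferred
gravimetrically: the bolus collected just before swallowing and the intact
cheese are both assayed for dry matter (DM) and water content (WC), and

    saliva content (%) = (bolus WC / bolus DM) x cheese DM - cheese WC

i.e. the water in excess of what the cheese itself would contribute at the
bolus's dry-matter level.  Saliva volume (mL) = content x 10^-2 x consumed
mass (g), treating saliva as water (> 99 % water by mass).

Boli are staged at 33 % (early), 66 % (late) and 99 % (swallowing point) of
each subject's own mastication time.

Panel summaries report group means with the population ("Pearson") standard
deviation, i.e. the divide-by-N convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionMeasure",
    "PanelistRecord",
    "DerivedParams",
    "chewing_frequency",
    "saliva_content",
    "saliva_volume",
    "stage_times",
    "derive_params",
    "summarize_panel",
]

GROUPS = ("child", "adult")
AGE_RANGES = {"child": (5, 12), "adult": (18, 65)}

#: Variables summarised per group, in report order.
SUMMARY_VARIABLES = (
    "mouth_volume",
    "quantity_consumed",
    "ratio_mouth_per_quantity",
    "mastication_time",
    "n_compressions",
    "chewing_frequency",
    "saliva_volume",
    "saliva_rate",
    "ratio_saliva_per_mouth",
    "ratio_saliva_per_quantity",
)


@dataclass(frozen=True)
class CompositionMeasure:
    """Dry matter and water content of a sample, in % of mass."""

    dry_matter: float
    water_content: float

    def __post_init__(self) -> None:
        for name, v in (("dry_matter", self.dry_matter),
                        ("water_content", self.water_content)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if abs(self.dry_matter + self.water_content - 100.0) > 0.5:
            raise ValueError(
                "dry_matter + water_content must equal 100 within 0.5, got "
                f"{self.dry_matter + self.water_content}"
            )


@dataclass
class PanelistRecord:
    """One subject's raw masticatory measurements (triplicates averaged)."""

    id: str
    group: str
    mouth_volume: float  # mL
    quantity_consumed: float  # g
    mastication_time: float  # s
    n_compressions: int
    bolus_composition: Optional[CompositionMeasure] = None
    cheese_composition: Optional[CompositionMeasure] = None
    saliva_volume_measured: Optional[float] = None  # mL, if assayed directly
    consumed_mass: float = 4.5  # g, standard piece weight
    age: Optional[float] = None
    gender: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("mouth_volume", "quantity_consumed", "mastication_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_compressions < 1:
            raise ValueError("n_compressions must be >= 1")
        if self.age is not None:
            lo, hi = AGE_RANGES[self.group]
            if not lo <= self.age <= hi:
                raise ValueError(
                    f"age {self.age} outside the {self.group} range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class DerivedParams:
    chewing_frequency: float  # compressions/s
    saliva_content: float  # %
    saliva_volume: float  # mL
    saliva_rate: float  # mL/s
    ratio_mouth_per_quantity: float  # mL/g
    ratio_saliva_per_mouth: float  # mL/mL
    ratio_saliva_per_quantity: float  # mL/g


def chewing_frequency(n_compressions: float, mastication_time: float) -> float:
    """Tongue–palate compressions per second."""
    if mastication_time <= 0:
        raise ValueError("mastication_time must be positive")
    if n_compressions < 0:
        raise ValueError("n_compressions must be nonnegative")
    return n_compressions / mastication_time


def saliva_content(
    bolus: CompositionMeasure, cheese: CompositionMeasure
) -> float:
    """Saliva mass fraction (%) of the bolus from DM/WC assays.

    (bolus WC / bolus DM) x cheese DM - cheese WC.  A negative result
    (bolus drier than the cheese, possible through evaporation or assay
    error) is clamped to 0 with a warning: a physical saliva volume cannot
    be negative.
    """
    if bolus.dry_matter <= 0:
        raise ValueError("bolus dry matter must be positive")
    content = (bolus.water_content / bolus.dry_matter) * cheese.dry_matter \
        - cheese.water_content
    if content < 0:
        warnings.warn(
            f"negative saliva content ({content:.3f}%) clamped to 0",
            stacklevel=2,
        )
        content = 0.0
    return content


def saliva_volume(content: float, consumed_mass: float = 4.5) -> float:
    """Saliva volume (mL) incorporated into the bolus.

    content x 10^-2 x consumed mass (g); grams of saliva are assimilated to
    millilitres since saliva is more than 99 % water.
    """
    if content < 0:
        raise ValueError("saliva content must be nonnegative")
    if consumed_mass <= 0:
        raise ValueError("consumed_mass must be positive")
    return content * 1e-2 * consumed_mass


def stage_times(mastication_time: float) -> tuple[float, float, float]:
    """Bolus-collection times at 33 / 66 / 99 % of one subject's chew time."""
    if mastication_time <= 0:
        raise ValueError("mastication_time must be positive")
    return (
        0.33 * mastication_time,
        0.66 * mastication_time,
        0.99 * mastication_time,
    )


def derive_params(record: PanelistRecord) -> DerivedParams:
    """All derived quantities for one subject.

    Saliva volume comes from the DM/WC assay when compositions are present,
    otherwise from ``saliva_volume_measured``.
    """
    if record.bolus_composition is not None and record.cheese_composition is not None:
        content = saliva_content(record.bolus_composition, record.cheese_composition)
        vol = saliva_volume(content, record.consumed_mass)
    elif record.saliva_volume_measured is not None:
        vol = record.saliva_volume_measured
        content = vol / (1e-2 * record.consumed_mass)
    else:
        raise ValueError(
            f"subject {record.id}: need bolus+cheese compositions or a "
            "measured saliva volume"
        )
    return DerivedParams(
        chewing_frequency=chewing_frequency(
            record.n_compressions, record.mastication_time
        ),
        saliva_content=content,
        saliva_volume=vol,
        saliva_rate=vol / record.mastication_time,
        ratio_mouth_per_quantity=record.mouth_volume / record.quantity_consumed,
        ratio_saliva_per_mouth=vol / record.mouth_volume,
        ratio_saliva_per_quantity=vol / record.quantity_consumed,
    )


def panel_frame(records: Sequence[PanelistRecord]) -> pd.DataFrame:
    """One row per subject with raw and derived parameters."""
    rows = []
    for rec in records:
        d = derive_params(rec)
        rows.append({
            "id": rec.id,
            "group": rec.group,
            "mouth_volume": rec.mouth_volume,
            "quantity_consumed": rec.quantity_consumed,
            "mastication_time": rec.mastication_time,
            "n_compressions": rec.n_compressions,
            "chewing_frequency": d.chewing_frequency,
            "saliva_content": d.saliva_content,
            "saliva_volume": d.saliva_volume,
            "saliva_rate": d.saliva_rate,
            "ratio_mouth_per_quantity": d.ratio_mouth_per_quantity,
            "ratio_saliva_per_mouth": d.ratio_saliva_per_mouth,
            "ratio_saliva_per_quantity": d.ratio_saliva_per_quantity,
        })
    return pd.DataFrame(rows)


def summarize_panel(records: Sequence[PanelistRecord]) -> pd.DataFrame:
    """Group mean ± population SD per variable, plus pooled overall means.

    Returns a tidy frame with columns (variable, group, mean, sd, n); the
    "overall" rows pool subjects across groups (with equal group sizes this
    equals the mean of the group means).
    """
    df = panel_frame(records)
    if df.empty:
        raise ValueError("empty panel")
    for g in GROUPS:
        if (df["group"] == g).sum() == 0:
            raise ValueError(f"no subjects in group {g!r}")

    out = []
    for var in SUMMARY_VARIABLES:
        for g in (*GROUPS, "overall"):
            sub = df if g == "overall" else df[df["group"] == g]
            vals = sub[var].to_numpy(dtype=float)
            out.append({
                "variable": var,
                "group": g,
                "mean": float(vals.mean()),
                "sd": float(vals.std()),  # population (divide by N)
                "n": int(len(vals)),
            })
    return pd.DataFrame(out)
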