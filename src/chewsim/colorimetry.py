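"""CIELAB colour representation and colour-difference (ΔE) computation.

Surface-colouring a homogeneous white cheese paste turns mixing during
chewing into a visible signal.  Whether the colouring itself is visible is
decided by the CIE76 colour difference ΔE between the uncoloured and
coloured product, measured with a chromameter in L*a*b* space:

    ΔE = sqrt(ΔL*² + Δa*² + Δb*²)

A difference above ~5 CIELAB units is detectable by a human observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["LabColor", "delta_e", "is_visually_distinct"]


@dataclass(frozen=True)
class LabColor:
    """A CIE L*a*b* triple.

    Parameters
    ----------
    L : float
        Lightness, in [0, 100].
    a : float
        Red–green opponent axis (positive = red).
    b : float
        Yellow–blue opponent axis (positive = yellow).
    """

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}* component: {v!r}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")


def delta_e(reference: LabColor, sample: LabColor) -> float:
    """CIE76 colour difference between two L*a*b* colours.

    Euclidean distance in L*a*b* space; symmetric in its arguments and zero
    iff the colours are componentwise equal.
    """
    return math.sqrt(
        (reference.L - sample.L) ** 2
        + (reference.a - sample.a) ** 2
        + (reference.b - sample.b) ** 2
    )


def is_visually_distinct(delta: float, threshold: float = 5.0) -> bool:
    """Whether a colour difference is noticeable to a human observer.

    Uses the strict rule ΔE > threshold (default 5 CIELAB units); a
    difference exactly at the threshold is judged not distinct.
    """
    if not math.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be a finite nonnegative number, got {delta!r}")
    return delta > threshold
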