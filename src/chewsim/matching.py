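"""Nearest-value matching of in vitro masticator settings to in vivo boli.

For each group (child/adult), mastication stage (33/66/99 %) and metric
(red-channel variance or back-extrusion hardness), the masticator setting
whose bolus measurement is closest in absolute value to the in vivo one is
selected.  Equidistant candidates are resolved by minimal intervention:
fewer compressions first, then lower rotation speed.  The final per-group
recommendation is the swallowing-stage (99 %) match under the image metric —
the bolus mixing state outranks hardness for mimicking in vivo chewing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .transposition import InVitroSetting

__all__ = [
    "METRICS",
    "StageMeasurement",
    "MatchResult",
    "MatchReport",
    "match_stage",
    "match_all",
]

METRICS = ("red_variance", "hardness")
GROUPS = ("child", "adult")
STAGES = (33, 66, 99)

#: Relative tolerance under which two candidate gaps count as tied (printed
#: table values carry ~4 significant digits; this absorbs float rounding).
_GAP_RTOL = 1e-9

Candidate = tuple[InVitroSetting, float]


@dataclass(frozen=True)
class StageMeasurement:
    """One measured value, tagged with its origin and metric."""

    origin: object  # (group, stage) tuple or an InVitroSetting
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.value < 0:
            raise ValueError("measurement values must be nonnegative")


@dataclass(frozen=True)
class MatchResult:
    group: Optional[str]
    stage: Optional[int]
    metric: str
    in_vivo_value: float
    selected: InVitroSetting
    in_vitro_value: float

    @property
    def absolute_gap(self) -> float:
        return abs(self.in_vivo_value - self.in_vitro_value)


def _tiebreak_key(setting: InVitroSetting) -> tuple[int, float]:
    return (setting.n_compressions, setting.rotation_speed)


def match_stage(
    in_vivo: StageMeasurement,
    candidates: Sequence[Union[Candidate, StageMeasurement]],
) -> MatchResult:
    """Select the candidate minimising |in vivo − in vitro|.

    Candidates are (InVitroSetting, value) pairs, or StageMeasurements whose
    origin is an InVitroSetting (their metric must then match the in vivo
    one).  Ties are broken by fewer compressions, then lower rpm.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    pairs: list[Candidate] = []
    for cand in candidates:
        if isinstance(cand, StageMeasurement):
            if cand.metric != in_vivo.metric:
                raise ValueError(
                    f"mixed metrics: {cand.metric!r} vs {in_vivo.metric!r}"
                )
            if not isinstance(cand.origin, InVitroSetting):
                raise ValueError("candidate origin must be an InVitroSetting")
            pairs.append((cand.origin, cand.value))
        else:
            setting, value = cand
            pairs.append((setting, float(value)))

    group, stage = (
        in_vivo.origin if isinstance(in_vivo.origin, tuple) else (None, None)
    )
    best: Optional[Candidate] = None
    best_gap = math.inf
    # tie-break order first, so ties keep the earlier candidate
    for setting, value in sorted(pairs, key=lambda c: _tiebreak_key(c[0])):
        gap = abs(in_vivo.value - value)
        tied = math.isclose(gap, best_gap, rel_tol=_GAP_RTOL, abs_tol=0.0)
        if gap < best_gap and not tied:
            best, best_gap = (setting, value), gap
    assert best is not None
    return MatchResult(
        group=group,
        stage=stage,
        metric=in_vivo.metric,
        in_vivo_value=in_vivo.value,
        selected=best[0],
        in_vitro_value=best[1],
    )


@dataclass(frozen=True)
class MatchReport:
    """All group x stage x metric matches plus per-group recommendations."""

    matches: tuple[MatchResult, ...]
    recommendations: Mapping[str, InVitroSetting]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": m.group,
                "stage": m.stage,
                "metric": m.metric,
                "in_vivo_value": m.in_vivo_value,
                "in_vitro_value": m.in_vitro_value,
                "absolute_gap": m.absolute_gap,
                "n_compressions": m.selected.n_compressions,
                "rotation_speed": m.selected.rotation_speed,
            }
            for m in self.matches
        )

    def to_markdown(self) -> str:
        lines = [
            "| Group | Stage (%) | Metric | In vivo | In vitro | Setting |",
            "|---|---|---|---|---|---|",
        ]
        for m in self.matches:
            setting = (
                f"{m.selected.n_compressions} compressions – "
                f"{m.selected.rotation_speed:g} rpm"
            )
            lines.append(
                f"| {m.group} | {m.stage} | {m.metric} | {m.in_vivo_value:g} "
                f"| {m.in_vitro_value:g} | {setting} |"
            )
        lines.append("")
        for group, s in self.recommendations.items():
            lines.append(
                f"**{group} recommendation:** {s.n_compressions} compressions "
                f"– {s.rotation_speed:g} rpm"
            )
        return "\n".join(lines)


def match_all(
    in_vivo: Mapping[tuple[str, int, str], float],
    in_vitro: Mapping[str, Sequence[Candidate]],
    *,
    priority_metric: str = "red_variance",
) -> MatchReport:
    """Match every group x stage x metric cell and recommend per group.

    Parameters
    ----------
    in_vivo : mapping (group, stage, metric) -> value; must cover all
        2 groups x 3 stages x 2 metrics cells.
    in_vitro : mapping metric -> candidate (setting, value) pairs.
    priority_metric : metric whose 99 % match becomes the per-group final
        recommendation (image analysis by default).
    """
    if priority_metric not in METRICS:
        raise ValueError(f"unknown priority metric {priority_metric!r}")
    missing = [
        (g, s, m)
        for g in GROUPS
        for s in STAGES
        for m in METRICS
        if (g, s, m) not in in_vivo
    ]
    if missing:
        raise ValueError(f"in vivo table incomplete; missing cells: {missing}")
    for m in METRICS:
        if m not in in_vitro or not in_vitro[m]:
            raise ValueError(f"no in vitro candidates for metric {m!r}")

    matches = []
    for g in GROUPS:
        for s in STAGES:
            for m in METRICS:
                meas = StageMeasurement(
                    origin=(g, s), metric=m, value=in_vivo[(g, s, m)]
                )
                matches.append(match_stage(meas, in_vitro[m]))

    recommendations = {
        g: next(
            m.selected
            for m in matches
            if m.group == g and m.stage == 99 and m.metric == priority_metric
        )
        for g in GROUPS
    }
    return MatchReport(matches=tuple(matches), recommendations=recommendations)
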