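"""Statistical machinery: one-way and mixed (split-plot) ANOVA, triangle test.

The designs supported are the ones an oral-processing panel study needs:

* one-way fixed-effect ANOVA (e.g. uncoloured vs coloured cheese);
* a mixed two-way ANOVA, subject (random, nested in group) + group (fixed),
  for per-subject masticatory parameters measured in triplicate;
* a mixed three-way ANOVA with interaction, subject (random, nested in
  group) + group + mastication progress + group × progress, for bolus image
  and texture measurements.

All sums of squares are Type III, computed from a full-rank sum-to-zero
contrast parameterisation by comparing the full model's residual sum of
squares with that of the model lacking the effect's columns.  The subject
stratum is the error term for the between-subject (group) effect; the
within-subject residual is the error term for progress and the interaction
(classical split-plot F ratios).

The triangle test is a forced choice among three samples with null success
probability 1/3; its p-value is the exact upper-tail binomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TriangleTestResult",
    "one_way_anova",
    "mixed_anova",
    "triangle_test",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass(frozen=True)
class TriangleTestResult:
    n_panelists: int
    n_correct: int
    p_value: float
    min_correct_for_alpha: Optional[int]  # None = unattainable at this n
    significant: bool


def _f_test(ss_num: float, df_num: float, ss_den: float, df_den: float,
            effect: str) -> AnovaResult:
    """F ratio with the degenerate zero-denominator convention."""
    ms_num = ss_num / df_num if df_num > 0 else 0.0
    ms_den = ss_den / df_den if df_den > 0 else 0.0
    if ms_den <= 0.0:
        if ms_num > 0.0:
            return AnovaResult(effect, float("inf"), df_num, df_den, 0.0)
        return AnovaResult(effect, 0.0, df_num, df_den, 1.0)
    f = ms_num / ms_den
    p = float(sps.f.sf(f, df_num, df_den))
    return AnovaResult(effect, float(f), float(df_num), float(df_den), p)


def one_way_anova(values: Sequence[float], group_labels: Sequence[str]) -> AnovaResult:
    """Classical one-way fixed-effect ANOVA (between/within decomposition)."""
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if y.shape != labels.shape or y.ndim != 1:
        raise ValueError("values and group_labels must be 1-D of equal length")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(y) <= len(groups):
        raise ValueError("need more observations than groups")

    grand = y.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in groups:
        yg = y[labels == g]
        if yg.size == 0:
            raise ValueError(f"group {g!r} has no observations")
        ss_between += yg.size * (yg.mean() - grand) ** 2
        ss_within += float(((yg - yg.mean()) ** 2).sum())
    df_between = len(groups) - 1
    df_within = len(y) - len(groups)
    return _f_test(ss_between, df_between, ss_within, df_within, "group")


# ---------------------------------------------------------------------------
# mixed (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _sum_to_zero(labels: np.ndarray, levels: Sequence) -> np.ndarray:
    """Full-rank sum-to-zero contrast columns (k levels -> k-1 columns)."""
    k = len(levels)
    cols = np.zeros((len(labels), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def mixed_anova(
    values: Sequence[float],
    subject_ids: Sequence,
    fixed_factors: Mapping[str, Sequence],
    interaction: bool = True,
) -> list[AnovaResult]:
    """Split-plot ANOVA with a random subject effect nested in the group.

    Parameters
    ----------
    values : 1-D response.
    subject_ids : subject identifier per observation.
    fixed_factors : name -> labels per observation.  Exactly one factor must
        be between-subject (constant within every subject); at most one may
        vary within subjects.
    interaction : include the between x within interaction.

    Returns
    -------
    One AnovaResult per fixed effect (between factor against the
    subject-within-group stratum; within factor and interaction against the
    within-subject residual), plus one for the subject stratum itself.
    """
    y = np.asarray(values, dtype=float)
    subj = np.asarray(subject_ids)
    if y.ndim != 1 or subj.shape != y.shape:
        raise ValueError("values and subject_ids must be 1-D of equal length")
    factors = {name: np.asarray(f) for name, f in fixed_factors.items()}
    for name, f in factors.items():
        if f.shape != y.shape:
            raise ValueError(f"factor {name!r} length mismatch")

    subjects = np.unique(subj)
    between, within = [], []
    for name, f in factors.items():
        constant_in_subject = all(
            len(np.unique(f[subj == s])) == 1 for s in subjects
        )
        (between if constant_in_subject else within).append(name)
    if len(between) != 1:
        raise ValueError(
            "exactly one fixed factor must be between-subject (constant "
            f"within every subject); found {between or 'none'}"
        )
    if len(within) > 1:
        raise ValueError("at most one within-subject factor is supported")

    a_name = between[0]
    a = factors[a_name]
    a_levels = list(np.unique(a))
    if len(a_levels) < 2:
        raise ValueError(f"between factor {a_name!r} needs >= 2 levels")

    blocks: dict[str, np.ndarray] = {a_name: _sum_to_zero(a, a_levels)}

    if within:
        b_name = within[0]
        b = factors[b_name]
        b_levels = list(np.unique(b))
        if len(b_levels) < 2:
            raise ValueError(f"within factor {b_name!r} needs >= 2 levels")
        blocks[b_name] = _sum_to_zero(b, b_levels)
        if interaction:
            ab = np.einsum(
                "ij,ik->ijk", blocks[a_name], blocks[b_name]
            ).reshape(len(y), -1)
            blocks[f"{a_name}:{b_name}"] = ab
    elif interaction and len(factors) == 1:
        interaction = False  # nothing to interact with

    # subject nested in group: per group, sum-to-zero over its subjects
    subj_cols = []
    for g in a_levels:
        g_subjects = list(np.unique(subj[a == g]))
        if len(g_subjects) < 2:
            raise ValueError(
                f"group {g!r} needs >= 2 subjects for a subject stratum"
            )
        cols = _sum_to_zero(subj, g_subjects)
        cols[a != g, :] = 0.0
        subj_cols.append(cols)
    blocks["subject"] = np.hstack(subj_cols)

    intercept = np.ones((len(y), 1))
    X_full = np.hstack([intercept] + list(blocks.values()))
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        raise ValueError("design is rank deficient (confounded factors)")
    df_resid = len(y) - rank_full
    if within and interaction:
        # the interaction is only separable from the subject x within-factor
        # error when cells carry replicate observations
        cells = {}
        for s, lev in zip(subj, factors[within[0]]):
            cells[(s, lev)] = cells.get((s, lev), 0) + 1
        if max(cells.values()) < 2:
            raise ValueError(
                "interaction requested with a single observation per "
                "subject x level cell: replicate observations are required"
            )
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom left")
    sse_full = _sse(X_full, y)

    # Type III SS: drop each block from the full model
    ss: dict[str, float] = {}
    for name, cols in blocks.items():
        X_red = np.hstack(
            [intercept] + [c for n, c in blocks.items() if n != name]
        )
        ss[name] = max(_sse(X_red, y) - sse_full, 0.0)

    df = {name: cols.shape[1] for name, cols in blocks.items()}
    ss_subj, df_subj = ss["subject"], df["subject"]

    results = [
        _f_test(ss[a_name], df[a_name], ss_subj, df_subj, a_name),
        _f_test(ss_subj, df_subj, sse_full, df_resid, "subject"),
    ]
    for name in blocks:
        if name in (a_name, "subject"):
            continue
        results.append(_f_test(ss[name], df[name], sse_full, df_resid, name))
    return results


# ---------------------------------------------------------------------------
# triangle test
# ---------------------------------------------------------------------------

def triangle_test(
    n_correct: int, n_panelists: int, alpha: float = 0.05
) -> TriangleTestResult:
    """Exact one-sided binomial triangle test (null success probability 1/3).

    p_value = P(X >= n_correct) under X ~ Binomial(n_panelists, 1/3);
    min_correct_for_alpha is the smallest count whose tail probability is
    <= alpha (None when even a perfect score is not significant).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= n_correct <= n_panelists:
        raise ValueError("need 0 <= n_correct <= n_panelists")

    p_value = float(sps.binom.sf(n_correct - 1, n_panelists, 1.0 / 3.0))
    min_correct: Optional[int] = None
    for k in range(n_panelists + 1):
        if sps.binom.sf(k - 1, n_panelists, 1.0 / 3.0) <= alpha:
            min_correct = k
            break
    return TriangleTestResult(
        n_panelists=n_panelists,
        n_correct=n_correct,
        p_value=p_value,
        min_correct_for_alpha=min_correct,
        significant=p_value <= alpha,
    )
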