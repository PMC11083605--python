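import math

import numpy as np
import pytest
from scipy import stats as sps

from chewsim.stats import mixed_anova, one_way_anova, triangle_test


def _balanced_splitplot(rng, n_subj=6, stages=(33, 66, 99), reps=2,
                        group_effect=0.0, stage_effect=0.0, subj_sd=1.0,
                        noise_sd=1.0):
    """Balanced two-group split-plot data with known effect sizes."""
    vals, subj, grp, stg = [], [], [], []
    for gi, g in enumerate(("child", "adult")):
        for si in range(n_subj):
            u = rng.normal(0.0, subj_sd)
            for ki, st in enumerate(stages):
                for _ in range(reps):
                    vals.append(
                        u
                        + group_effect * (gi - 0.5)
                        + stage_effect * (ki - 1)
                        + rng.normal(0.0, noise_sd)
                    )
                    subj.append(f"{g}{si}")
                    grp.append(g)
                    stg.append(st)
    return np.array(vals), np.array(subj), np.array(grp), np.array(stg)


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0)

    def test_zero_within_variance_gives_infinite_f(self):
        res = one_way_anova([0, 0, 1, 1], ["a", "a", "b", "b"])
        assert math.isinf(res.F)
        assert res.p == 0.0

    def test_matches_brute_force_decomposition(self, rng):
        y = rng.normal(0, 1, 30)
        labels = rng.choice(["a", "b", "c"], 30)
        res = one_way_anova(y, labels)
        # independent SS oracle
        grand = y.mean()
        ss_b = sum((y[labels == g]).size * (y[labels == g].mean() - grand) ** 2
                   for g in set(labels))
        ss_w = sum(((y[labels == g] - y[labels == g].mean()) ** 2).sum()
                   for g in set(labels))
        f_oracle = (ss_b / 2) / (ss_w / (30 - 3))
        assert res.F == pytest.approx(f_oracle, rel=1e-12)
        # library cross-check
        f_scipy, p_scipy = sps.f_oneway(*(y[labels == g] for g in set(labels)))
        assert res.F == pytest.approx(float(f_scipy), rel=1e-10)
        assert res.p == pytest.approx(float(p_scipy), rel=1e-9)

    def test_p_consistent_with_f_distribution(self, rng):
        res = one_way_anova(rng.normal(0, 1, 20), ["a"] * 10 + ["b"] * 10)
        assert res.p == pytest.approx(
            float(sps.f.sf(res.F, res.df_num, res.df_den)), abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0], ["a", "b"])


class TestMixedAnova:
    def test_group_f_equals_oneway_on_subject_means(self, rng):
        """Split-plot oracle: on a balanced design, the between-subject F
        equals a one-way ANOVA on per-subject means."""
        vals, subj, grp, stg = _balanced_splitplot(rng, group_effect=1.0)
        res = {r.effect: r for r in
               mixed_anova(vals, subj, {"group": grp, "stage": stg})}
        subj_means = {s: vals[subj == s].mean() for s in np.unique(subj)}
        means_by_group = [
            [m for s, m in subj_means.items() if s.startswith(g)]
            for g in ("child", "adult")
        ]
        f_oracle, p_oracle = sps.f_oneway(*means_by_group)
        assert res["group"].F == pytest.approx(float(f_oracle), rel=1e-9)
        assert res["group"].p == pytest.approx(float(p_oracle), rel=1e-6)

    def test_balanced_design_matches_classical_mean_squares(self, rng):
        """Closed-form EMS oracle computed from cell means on a balanced
        2 x 3 design with replicates."""
        vals, subj, grp, stg = _balanced_splitplot(
            rng, group_effect=0.8, stage_effect=0.6
        )
        res = {r.effect: r for r in
               mixed_anova(vals, subj, {"group": grp, "stage": stg})}

        groups, stages = np.unique(grp), np.unique(stg)
        n_subj = len(np.unique(subj)) // len(groups)
        reps = len(vals) // (len(groups) * n_subj * len(stages))
        grand = vals.mean()
        cell = {(g, s): vals[(grp == g) & (stg == s)].mean()
                for g in groups for s in stages}
        gm = {g: vals[grp == g].mean() for g in groups}
        sm = {s: vals[stg == s].mean() for s in stages}
        per_group_n = n_subj * len(stages) * reps
        ss_group = per_group_n * sum((gm[g] - grand) ** 2 for g in groups)
        ss_stage = (len(groups) * n_subj * reps
                    * sum((sm[s] - grand) ** 2 for s in stages))
        ss_int = n_subj * reps * sum(
            (cell[(g, s)] - gm[g] - sm[s] + grand) ** 2
            for g in groups for s in stages
        )
        subj_mean = {s: vals[subj == s].mean() for s in np.unique(subj)}
        ss_subj = len(stages) * reps * sum(
            (subj_mean[s] - gm[g]) ** 2
            for g in groups for s in np.unique(subj[grp == g])
        )
        df_subj = len(groups) * (n_subj - 1)
        # residual df for the full model: N - [1 + (g-1) + (s-1) +
        # (g-1)(s-1) + g(n-1)]
        df_resid = len(vals) - (
            1 + (len(groups) - 1) + (len(stages) - 1)
            + (len(groups) - 1) * (len(stages) - 1)
            + len(groups) * (n_subj - 1)
        )
        # pooled residual: subject x stage variation plus replicate error
        total = float(((vals - vals.mean()) ** 2).sum())
        sse = total - (ss_group + ss_stage + ss_int + ss_subj)

        assert res["group"].F == pytest.approx(
            (ss_group / (len(groups) - 1)) / (ss_subj / df_subj), rel=1e-9
        )
        assert res["stage"].F == pytest.approx(
            (ss_stage / (len(stages) - 1)) / (sse / df_resid), rel=1e-9
        )
        assert res["group:stage"].F == pytest.approx(
            (ss_int / ((len(groups) - 1) * (len(stages) - 1)))
            / (sse / df_resid), rel=1e-9
        )

    def test_sums_of_squares_conserve_total(self, rng):
        """On a balanced (orthogonal) design the Type III components plus
        residual reconstruct the total sum of squares."""
        vals, subj, grp, stg = _balanced_splitplot(rng, group_effect=0.5)
        total = float(((vals - vals.mean()) ** 2).sum())
        from chewsim.stats import _sse, _sum_to_zero
        inter = np.ones((len(vals), 1))
        a = _sum_to_zero(grp, list(np.unique(grp)))
        b = _sum_to_zero(stg, list(np.unique(stg)))
        ab = np.einsum("ij,ik->ijk", a, b).reshape(len(vals), -1)
        subj_cols = []
        for g in np.unique(grp):
            cols = _sum_to_zero(subj, list(np.unique(subj[grp == g])))
            cols[grp != g, :] = 0.0
            subj_cols.append(cols)
        S = np.hstack(subj_cols)
        X = np.hstack([inter, a, b, ab, S])
        sse = _sse(X, vals)
        parts = []
        for drop in (a, b, ab, S):
            keep = [blk for blk in (a, b, ab, S) if blk is not drop]
            parts.append(_sse(np.hstack([inter] + keep), vals) - sse)
        assert sum(parts) + sse == pytest.approx(total, rel=1e-9)

    def test_null_type_one_error_calibrated(self):
        """Empirical size of the between-subject test near the nominal 5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            vals, subj, grp, stg = _balanced_splitplot(rng)
            res = mixed_anova(vals, subj, {"group": grp, "stage": stg})
            p = next(r.p for r in res if r.effect == "group")
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.08

    def test_power_at_large_stage_effect(self):
        """A pure, strong stage effect is detected at p < 0.001 nearly always."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            vals, subj, grp, stg = _balanced_splitplot(
                rng, stage_effect=2.0, noise_sd=0.5, subj_sd=0.5
            )
            res = mixed_anova(vals, subj, {"group": grp, "stage": stg})
            p = next(r.p for r in res if r.effect == "stage")
            hits += p < 1e-3
        assert hits / n_sims >= 0.95

    def test_single_observation_per_cell_with_interaction_rejected(self, rng):
        vals, subj, grp, stg = _balanced_splitplot(rng, reps=1)
        with pytest.raises(ValueError, match="replicate"):
            mixed_anova(vals, subj, {"group": grp, "stage": stg})

    def test_two_between_factors_rejected(self, rng):
        vals, subj, grp, stg = _balanced_splitplot(rng)
        with pytest.raises(ValueError, match="between-subject"):
            mixed_anova(vals, subj, {"group": grp, "also_group": grp})


class TestTriangleTest:
    @staticmethod
    def _tail_oracle(k, n, p=1.0 / 3.0):
        """Upper-tail binomial by recursive term ratios (independent route)."""
        if k <= 0:
            return 1.0
        term = (1 - p) ** n  # P(X = 0)
        # advance to P(X = k)
        for j in range(k):
            term *= (n - j) / (j + 1) * (p / (1 - p))
        total = 0.0
        for j in range(k, n + 1):
            total += term
            if j < n:
                term *= (n - j) / (j + 1) * (p / (1 - p))
        return total

    @pytest.mark.parametrize("k", [0, 1, 5, 9, 10, 15, 16, 20, 30])
    def test_matches_recursive_summation_oracle(self, k):
        res = triangle_test(k, 30)
        assert res.p_value == pytest.approx(self._tail_oracle(k, 30),
                                            abs=1e-12)

    @pytest.mark.parametrize("n_correct", [5, 9])
    def test_published_session_counts_not_significant(self, n_correct):
        res = triangle_test(n_correct, 30)
        assert not res.significant
        assert res.p_value > 0.05

    def test_perfect_score_probability(self):
        res = triangle_test(30, 30)
        assert res.significant
        assert res.p_value == pytest.approx((1.0 / 3.0) ** 30, rel=1e-9)

    def test_minimum_significant_count_at_thirty_panelists(self):
        """The exact binomial requires 15 of 30 at alpha = 0.05."""
        res = triangle_test(10, 30)
        assert res.min_correct_for_alpha == 15
        assert triangle_test(15, 30).significant
        assert not triangle_test(14, 30).significant

    def test_unattainable_significance_at_tiny_panel(self):
        assert triangle_test(2, 2).min_correct_for_alpha is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            triangle_test(5, 30, alpha=0.0)
        with pytest.raises(ValueError):
            triangle_test(31, 30)
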