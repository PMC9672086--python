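"""Trend test, variance test, tau-b, verdicts and the mixed ANOVA."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from bedmot.ordinal_stats import (
    StatError,
    TauResult,
    TrendTestResult,
    VarianceTestResult,
    brown_forsythe,
    composite_decision,
    cronbach_alpha,
    effect_size_verdict,
    jonckheere_terpstra,
    kendall_tau_b,
    mixed_anova,
    normality_check,
    p_stars,
)


def jt_brute_force_p(groups):
    """Exact two-sided permutation p by enumerating pooled-value permutations.

    Independent of the implementation: every permutation of the pooled
    values is assigned to the fixed group layout and J computed by a
    double loop.
    """
    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]

    def j_stat(values):
        J = 0.0
        bounds = np.cumsum([0] + sizes)
        for gi in range(len(sizes)):
            for gj in range(gi + 1, len(sizes)):
                for a in values[bounds[gi]:bounds[gi + 1]]:
                    for b in values[bounds[gj]:bounds[gj + 1]]:
                        J += 1.0 if b > a else (0.5 if b == a else 0.0)
        return J

    j_obs = j_stat(pooled)
    all_j = [j_stat(p) for p in itertools.permutations(pooled)]
    mu = float(np.mean(all_j))
    return float(np.mean([abs(j - mu) >= abs(j_obs - mu) - 1e-9 for j in all_j]))


class TestJonckheereTerpstra:
    def test_exhaustive_p_matches_brute_force_enumeration(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = jonckheere_terpstra(groups, method="permutation", seed=0)
        assert res.method == "exhaustive"
        assert res.z > 0
        assert res.p == pytest.approx(jt_brute_force_p(groups))

    def test_exhaustive_p_matches_brute_force_with_ties(self):
        groups = [[1, 1, 2], [2, 3], [3, 3]]
        res = jonckheere_terpstra(groups, method="permutation", seed=0)
        assert res.method == "exhaustive"
        assert res.p == pytest.approx(jt_brute_force_p(groups))

    def test_identical_observations(self):
        res = jonckheere_terpstra([[4, 4], [4, 4, 4]])
        assert res.z == 0.0 and res.p == 1.0

    def test_reversal_negates_z(self, rng):
        groups = [rng.normal(loc=m, size=8) for m in (0, 1, 2)]
        fwd = jonckheere_terpstra(groups)
        rev = jonckheere_terpstra(groups[::-1])
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p == pytest.approx(rev.p)

    def test_empty_group_rejected(self):
        with pytest.raises(StatError):
            jonckheere_terpstra([[1, 2], []])

    def test_descending_trend_negative(self):
        res = jonckheere_terpstra([[5, 6], [3, 4], [1, 2]])
        assert res.z < 0

    def test_monte_carlo_branch_close_to_normal_approx(self, rng):
        groups = [rng.normal(size=20) for _ in range(3)]
        na = jonckheere_terpstra(groups)
        mc = jonckheere_terpstra(groups, method="permutation", n_perm=20000, seed=5)
        assert mc.method == "permutation"
        assert abs(na.p - mc.p) <= 0.02


class TestBrownForsythe:
    def test_constant_groups(self):
        res = brown_forsythe([[3, 3, 3], [7, 7, 7]])
        assert res.F == 0.0 and res.p == 1.0 and res.homoscedastic

    def test_dfs(self):
        res = brown_forsythe([[1, 2, 3], [4, 5, 6, 7], [8, 9]])
        assert (res.df1, res.df2) == (2, 6)

    def test_matches_scipy_levene(self, rng):
        groups = [rng.normal(size=30), rng.normal(scale=2, size=25)]
        res = brown_forsythe(groups)
        F, p = stats.levene(*groups, center="median")
        assert res.F == pytest.approx(F) and res.p == pytest.approx(p)

    def test_detects_tenfold_spread(self, rng):
        hits = 0
        for _ in range(40):
            g1 = rng.normal(size=30)
            g2 = g1 * 10
            hits += brown_forsythe([g1, g2]).p < 0.05
        assert hits >= 38  # >= 95% power at this spread

    def test_small_group_rejected(self):
        with pytest.raises(StatError):
            brown_forsythe([[1], [2, 3]])


def tau_brute_force(x, y):
    """O(n^2) pair classification with the standard tie corrections."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / math.sqrt((n0 - ties_x) * (n0 - ties_y))


class TestKendallTau:
    def test_perfect_association(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40], B=50, seed=0).tau_b == 1.0
        assert kendall_tau_b([1, 2, 3, 4], [40, 30, 20, 10], B=50, seed=0).tau_b == -1.0

    def test_tied_example_matches_brute_force(self):
        x, y = [1, 1, 2, 3], [2, 1, 1, 3]
        res = kendall_tau_b(x, y, B=50, seed=0)
        assert res.tau_b == pytest.approx(tau_brute_force(x, y), abs=1e-12)

    def test_degenerate_margin(self):
        res = kendall_tau_b([1, 1, 1], [1, 2, 3], B=50, seed=0)
        assert res.degenerate and res.reason

    def test_antisymmetric_under_negating_y(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.normal(size=30)
        a = kendall_tau_b(x, y, B=50, seed=1)
        b = kendall_tau_b(x, -y, B=50, seed=1)
        assert a.tau_b == pytest.approx(-b.tau_b)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.integers(0, 3, 40).astype(float)
        a = kendall_tau_b(x, y, B=50, seed=1).tau_b
        b = kendall_tau_b(np.exp(x), y * 7 + 2, B=50, seed=1).tau_b
        assert a == pytest.approx(b)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        res = kendall_tau_b(x, y, B=1000, seed=3)
        assert res.ci_low <= res.tau_b <= res.ci_high

    def test_counts_bootstrap_agrees_with_pairwise_resampling(self, rng):
        from bedmot.ordinal_stats import _tau_b_batch, _tau_b_bootstrap_draws

        x = rng.normal(size=50)
        y = rng.integers(0, 4, 50).astype(float)
        d1 = _tau_b_bootstrap_draws(x, y, 3000, np.random.default_rng(1))
        idx = np.random.default_rng(2).integers(0, 50, (3000, 50))
        d2 = _tau_b_batch(x[idx], y[idx])
        q1 = np.nanpercentile(d1, [2.5, 50, 97.5])
        q2 = np.nanpercentile(d2, [2.5, 50, 97.5])
        assert np.max(np.abs(q1 - q2)) < 0.03

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatError):
            kendall_tau_b([1, 2], [1, 2, 3])


def make_tau(tau, lo, hi, degenerate=False):
    return TauResult(tau_b=tau, ci_low=lo, ci_high=hi, n=100, degenerate=degenerate,
                     reason="degenerate" if degenerate else None)


class TestVerdicts:
    def test_published_style_effect(self):
        ok, stars, _ = effect_size_verdict(make_tau(0.31, 0.20, 0.42))
        assert ok and stars == 1

    def test_below_rmpe(self):
        ok, stars, reason = effect_size_verdict(make_tau(0.15, 0.05, 0.25))
        assert not ok and stars == 0 and "RMPE" in reason

    def test_inverse_significance_guard(self):
        ok, _, reason = effect_size_verdict(make_tau(0.25, -0.25, 0.55))
        assert not ok and "guard" in reason

    def test_one_sided_ci_reach_is_fine(self):
        # lower bound deep below -0.2 but upper below +0.2: still significant
        ok, stars, _ = effect_size_verdict(make_tau(-0.31, -0.66, 0.04))
        assert ok and stars == 1

    def test_star_ladder(self):
        assert effect_size_verdict(make_tau(0.55, 0.4, 0.7))[1] == 2
        assert effect_size_verdict(make_tau(0.85, 0.7, 0.95))[1] == 3

    def test_degenerate_tau(self):
        ok, stars, reason = effect_size_verdict(make_tau(0, 0, 0, degenerate=True))
        assert not ok and reason

    @pytest.mark.parametrize("p_trend,tau,expected_overall", [
        (0.001, 0.31, True),
        (0.2, 0.31, False),
        (0.01, 0.10, False),
    ])
    def test_composite_conjunction(self, p_trend, tau, expected_overall):
        trend = TrendTestResult(statistic=0, z=3.0, p=p_trend, method="normal_approx")
        variance = VarianceTestResult(F=0.5, df1=2, df2=100, p=0.6)
        verdict = composite_decision(trend, variance, make_tau(tau, tau - 0.1, tau + 0.1))
        assert verdict.overall == expected_overall
        assert verdict.homoscedastic

    def test_composite_monotone_in_p_and_tau(self):
        variance = VarianceTestResult(F=0.5, df1=2, df2=100, p=0.6)

        def overall(p, tau):
            trend = TrendTestResult(statistic=0, z=3.0, p=p, method="normal_approx")
            return composite_decision(trend, variance, make_tau(tau, tau - 0.1, tau + 0.1)).overall

        assert overall(0.04, 0.25)
        assert overall(0.01, 0.25)   # better p never flips to false
        assert overall(0.04, 0.45)   # larger effect never flips to false

    def test_medians_extend_requires_homoscedasticity(self):
        trend = TrendTestResult(statistic=0, z=3.0, p=0.001, method="normal_approx")
        hetero = VarianceTestResult(F=5.0, df1=2, df2=100, p=0.01)
        verdict = composite_decision(trend, hetero, make_tau(0.31, 0.2, 0.42))
        assert verdict.overall and not verdict.medians_extend

    def test_p_stars(self):
        assert [p_stars(p) for p in (0.2, 0.05, 0.01, 0.0005)] == ["", "*", "**", "***"]


class TestMixedAnova:
    def test_no_change_anywhere(self):
        pre = [1.0, 2, 3, 4, 5, 6]
        res = mixed_anova(pre, pre, ["a", "a", "a", "b", "b", "b"])
        assert res.F == 0.0 and res.p == 1.0

    def test_equivalent_to_anova_on_change_scores(self, rng):
        # with two timepoints the interaction test reduces to a one-way
        # ANOVA on post - pre; scipy provides the independent oracle
        pre = rng.normal(10, 2, 45)
        post = pre - rng.normal(2, 1, 45)
        grp = np.repeat(["a", "b", "c"], 15)
        res = mixed_anova(pre, post, grp)
        diffs = post - pre
        F_ref, p_ref = stats.f_oneway(*[diffs[grp == g] for g in "abc"])
        assert res.F == pytest.approx(F_ref)
        assert res.p == pytest.approx(p_ref)
        assert (res.numDF, res.denDF) == (2, 42)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        pre = rng.normal(size=30)
        post = pre + rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        res = mixed_anova(pre, post, grp)
        long = pd.DataFrame({
            "subject": np.tile(np.arange(30), 2),
            "time": np.repeat(["pre", "post"], 30),
            "score": np.concatenate([pre, post]),
            "group": np.tile(grp, 2),
        })
        ref = pingouin.mixed_anova(long, dv="score", within="time",
                                   subject="subject", between="group")
        inter = ref[ref.Source == "Interaction"].iloc[0]
        assert res.F == pytest.approx(inter.F)
        assert res.p == pytest.approx(inter["p_unc"])

    def test_detects_group_specific_change(self, rng):
        hits = 0
        for _ in range(30):
            pre = rng.normal(10, 1, 60)
            delta = np.where(np.repeat([0, 1, 2], 20) == 2, 1.0, 0.0)
            post = pre - delta + rng.normal(0, 1, 60)
            hits += mixed_anova(pre, post, np.repeat([0, 1, 2], 20)).p < 0.05
        assert hits >= 27  # >= 90% power at a 1 SD group-specific shift

    def test_small_group_rejected(self):
        with pytest.raises(StatError):
            mixed_anova([1, 2, 3], [1, 2, 3], ["a", "a", "b"])

    def test_nan_pairs_dropped(self):
        pre = [1.0, 2, np.nan, 4, 5, 6, 7, 8]
        post = [1.0, 2, 3, np.nan, 5, 6, 7, 8]
        res = mixed_anova(pre, post, ["a"] * 4 + ["b"] * 4)
        assert res.denDF == 4  # 6 usable subjects, 2 groups


class TestNormalityAndAlpha:
    def test_normal_samples_usually_pass(self, rng):
        passes = sum(normality_check(rng.normal(size=100))[1] > 0.05 for _ in range(30))
        assert passes >= 27

    def test_skewed_samples_usually_fail(self, rng):
        fails = sum(normality_check(rng.exponential(size=100))[1] < 0.05 for _ in range(30))
        assert fails >= 29

    def test_constant_sample_rejected(self):
        with pytest.raises(StatError):
            normality_check([2.0] * 10)

    def test_detrended_qq_near_zero_for_exact_normal_scores(self):
        x = stats.norm.ppf((np.arange(1, 101) - 0.375) / 100.25)
        _, _, detrended = normality_check(x)
        assert np.max(np.abs(detrended)) < 0.1

    def test_cronbach_alpha_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        latent = rng.normal(size=60)
        items = latent[:, None] + rng.normal(scale=1.0, size=(60, 7))
        mine = cronbach_alpha(items)
        ref = pingouin.cronbach_alpha(pd.DataFrame(items))[0]
        assert mine == pytest.approx(ref)

    def test_cronbach_alpha_high_for_parallel_items(self, rng):
        latent = rng.normal(size=200)
        items = latent[:, None] + rng.normal(scale=0.3, size=(200, 7))
        assert cronbach_alpha(items) > 0.9
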