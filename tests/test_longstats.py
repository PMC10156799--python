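"""Nonparametric tests against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from fontanflow import (LongitudinalRecord, annualized_delta, group_compare,
                        linear_fit, paired_change_test, posthoc_power,
                        rank_correlation, run_longitudinal_analysis)
from fontanflow.phantom import make_longitudinal_cohort


def ranksum_exact_p(a, b):
    """Enumeration oracle: two-sided p over all C(n+m, n) group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    sums = np.array([sum(ranks[list(c)]) for c in
                     itertools.combinations(range(len(pooled)), n)])
    mean = sums.mean()
    return float((np.abs(sums - mean) >= abs(obs - mean) - 1e-12).mean())


def signrank_exact_p(deltas):
    """Enumeration oracle: two-sided p over all 2^n sign assignments."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    mean = total / 2.0
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats, dtype=float)
    return float((np.abs(stats - mean) >= abs(obs - mean) - 1e-12).mean())


class TestAnnualizedDelta:
    def _record(self, base, follow, years):
        return LongitudinalRecord(subject_id="s", followup_years=years,
                                  baseline={("IVC", "m"): base},
                                  followup={("IVC", "m"): follow})

    @pytest.mark.parametrize("base,follow,years,expected", [
        (1.0, 3.0, 2.0, 1.0),
        (2.5, 2.5, 3.0, 0.0),
        (0.5, 0.4, 0.83, (0.4 - 0.5) / 0.83),   # -0.12048.../year
    ])
    def test_arithmetic(self, base, follow, years, expected):
        rec = self._record(base, follow, years)
        assert annualized_delta(rec, "m", "IVC") == pytest.approx(expected, rel=1e-12)

    def test_short_followup_rejected(self):
        with pytest.raises(ValueError):
            self._record(1.0, 2.0, 0.4)

    def test_missing_metric_rejected(self):
        rec = self._record(1.0, 2.0, 1.0)
        with pytest.raises(KeyError):
            annualized_delta(rec, "other", "IVC")


class TestGroupCompare:
    def test_complete_separation_exact_p(self):
        # {1,2,3} vs {10,11,12}: 2 of 20 orderings as extreme -> p = 0.1
        res = group_compare([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "ranksum_exact"

    def test_identical_groups_give_p_one(self):
        res = group_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 6)
        res = group_compare(a, b)
        assert res.p_value == pytest.approx(ranksum_exact_p(a, b), abs=1e-10)

    def test_exact_and_normal_approximation_agree_at_n10(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        exact = group_compare(a, b).p_value
        from scipy import stats
        approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(exact - approx) < 0.02

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0, 3.0])


class TestPairedChange:
    def test_all_concordant_ten_signs(self):
        # 10 positive deltas: p = 2/2^10
        res = paired_change_test(np.arange(1, 11, dtype=float))
        assert res.p_value == pytest.approx(2 / 1024, abs=1e-12)

    def test_symmetric_pairs_give_p_one(self):
        res = paired_change_test([1.0, -1.5, 2.0, -2.5])
        assert res.p_value > 0.6

    def test_single_nonzero_delta_gives_p_one(self):
        res = paired_change_test([0.7])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1, 6)
        res = paired_change_test(d)
        assert res.p_value == pytest.approx(signrank_exact_p(d), abs=1e-10)

    def test_all_zero_deltas_rejected(self):
        with pytest.raises(ValueError):
            paired_change_test([0.0, 0.0, 0.0])


class TestRankCorrelation:
    def test_perfect_monotone_data(self):
        x = np.arange(10.0)
        assert rank_correlation(x, x).statistic == pytest.approx(1.0)
        assert rank_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_rho_matches_direct_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 1.8, 9.0])
        # no ties: rho = 1 - 6*sum(d^2)/(n*(n^2-1))
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = ((rx - ry) ** 2).sum()
        oracle = 1 - 6 * d2 / (7 * 48)
        assert rank_correlation(x, y).statistic == pytest.approx(oracle, rel=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=7)
        y = 0.5 * x + rng.normal(size=7)
        base = rank_correlation(x, y)
        warped = rank_correlation(np.exp(x), y ** 3 if np.all(y > 0) else
                                  np.sign(y) * np.abs(y) ** 3)
        assert warped.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_p_on_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        res = rank_correlation(x, y)
        # oracle: enumerate all 120 pairings directly
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        obs = np.corrcoef(rx, ry)[0, 1]
        rhos = [np.corrcoef(rx[list(p)], ry)[0, 1]
                for p in itertools.permutations(range(5))]
        oracle = np.mean(np.abs(rhos) >= abs(obs) - 1e-12)
        assert res.p_value == pytest.approx(oracle, abs=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        res = linear_fit(x, 2 * x + 1)
        assert res.statistic == pytest.approx(2.0)
        assert res.effect == pytest.approx(1.0)

    def test_four_point_set_against_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        X = np.stack([np.ones_like(x), x], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        res = linear_fit(x, y)
        assert res.statistic == pytest.approx(beta[1], rel=1e-12)
        assert res.effect == pytest.approx(r2, rel=1e-12)

    def test_independent_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert linear_fit(x, y).effect < 0.01

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = 1.5 * x + rng.normal(size=20)
        r2 = linear_fit(x, y).effect
        r2b = linear_fit(5 * x - 3, -2 * y + 7).effect
        assert r2b == pytest.approx(r2, rel=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPosthocPower:
    def test_null_effect_power_is_alpha(self):
        p = posthoc_power("ranksum", n_a=10, n_b=10, mean_a=0, mean_b=0,
                          n_sims=2000, seed=0)
        assert abs(p - 0.05) < 0.025

    def test_huge_effect_power_is_one(self):
        p = posthoc_power("ranksum", n_a=5, n_b=5, mean_a=0, mean_b=10,
                          n_sims=1000, seed=1)
        assert p > 0.95

    def test_moderate_effect_matches_independent_simulation(self):
        # d = 1.0, n = 5/5: two Monte-Carlo estimates with different seeds
        p1 = posthoc_power("ranksum", n_a=5, n_b=5, mean_b=1.0,
                           n_sims=4000, seed=11)
        p2 = posthoc_power("ranksum", n_a=5, n_b=5, mean_b=1.0,
                           n_sims=4000, seed=99)
        assert abs(p1 - p2) < 0.03

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError):
            posthoc_power("ranksum", n_a=5, n_b=5, n_sims=100)


class TestCohortPipeline:
    def test_analysis_runs_on_synthetic_cohort(self):
        df = make_longitudinal_cohort(n_subjects=10, seed=7)
        res = run_longitudinal_analysis(df, seed=0, power_sims=1000)
        assert res.attrs["n_subjects"] == 10
        assert (res["p_value"].dropna() >= 0).all()
        assert (res["p_value"].dropna() <= 1).all()
        assert {"change_from_baseline", "unequal_vs_equal_fd"} <= \
            set(res["analysis"].unique())
        ols = res[res["analysis"].str.startswith("ols_")]
        assert len(ols) == 2
        assert ((ols["effect"] >= 0) & (ols["effect"] <= 1)).all()

    def test_el_deltas_track_peak_velocity_deltas(self):
        # the generator couples EL changes to peak-velocity changes
        df = make_longitudinal_cohort(n_subjects=10, seed=3)
        res = run_longitudinal_analysis(df, seed=0, power_sims=1000)
        ols = res[res["analysis"] == "ols_del_tot_vs_dpeak"]
        assert float(ols["effect"].iloc[0]) > 0.2
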