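"""Mixed ANOVA, permutation inference, FDR, correlations, cluster correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from psiloconn.stats import (assumption_checks, cluster_correct,
                             critical_threshold, delta_response, fdr_adjust,
                             normalized_relapse, permutation_anova, rho_to_t,
                             rm_anova, spearman_rho)


def _groups(n_ade, n_con):
    return ("ADE",) * n_ade + ("control",) * n_con


class TestDeltaResponse:
    def test_equal_epochs_give_zero(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        assert (delta_response(x, x) == 0).all()

    def test_sign_flips_under_swap(self):
        a = pd.Series([1.0, 2.0])
        b = pd.Series([0.5, 3.0])
        pd.testing.assert_series_equal(delta_response(a, b), -delta_response(b, a))

    def test_numeric_oracle_and_alignment_error(self):
        a = np.array([3.0, 5.0])
        b = np.array([1.0, 1.5])
        np.testing.assert_allclose(delta_response(a, b), [2.0, 3.5])
        with pytest.raises(ValueError):
            delta_response(pd.Series([1.0], index=["a"]),
                           pd.Series([1.0], index=["b"]))


class TestRmAnova:
    def test_df_for_two_group_crossover(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.normal(size=21), rng.normal(size=21), _groups(15, 6))
        assert res["treatment"].df == (1, 19)
        assert res["interaction"].df == (1, 19)

    def test_matches_pingouin_mixed_anova_balanced(self):
        """Cross-check against pingouin's mixed between-within ANOVA (the
        packages agree exactly for balanced groups; for unbalanced groups
        pingouin weights group means by size whereas this package keeps the
        MATLAB/Type-III unweighted-means convention)."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        n_ade = n_con = 8
        n = n_ade + n_con
        dpsi = rng.normal(size=n) + 0.3
        dsal = rng.normal(size=n)
        res = rm_anova(dpsi, dsal, _groups(n_ade, n_con))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "treatment": ["psi", "sal"] * n,
            "group": np.repeat([g for g in _groups(n_ade, n_con)], 2),
            "y": np.column_stack([dpsi, dsal]).ravel(),
        })
        aov = pg.mixed_anova(df, dv="y", within="treatment",
                             subject="subject", between="group")
        f_treat = aov.loc[aov.Source == "treatment", "F"].item()
        f_inter = aov.loc[aov.Source == "Interaction", "F"].item()
        assert res["treatment"].f == pytest.approx(f_treat, rel=1e-6)
        assert res["interaction"].f == pytest.approx(f_inter, rel=1e-6)

    def test_matches_effect_coded_ols_unbalanced(self):
        """For unbalanced groups both effects equal squared t statistics of
        an effect-coded OLS fit of the session difference (statsmodels)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        dpsi = rng.normal(size=21) + 0.3
        dsal = rng.normal(size=21)
        groups = _groups(15, 6)
        res = rm_anova(dpsi, dsal, groups)
        d = dpsi - dsal
        X = sm.add_constant(np.where([g == "ADE" for g in groups], 1.0, -1.0))
        fit = sm.OLS(d, X).fit()
        assert res["treatment"].f == pytest.approx(fit.tvalues[0]**2, rel=1e-8)
        assert res["interaction"].f == pytest.approx(fit.tvalues[1]**2, rel=1e-8)
        assert fit.df_resid == 19

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            res = rm_anova(rng.normal(size=21), rng.normal(size=21),
                           _groups(15, 6))
            rejections += res["treatment"].p_param < 0.05
        lo, hi = sps.binom.interval(0.95, n_sim, 0.05)
        assert lo <= rejections <= hi

    def test_power_for_large_shift(self):
        """An additive treatment shift of two noise SDs is detected at
        p < 0.01 in at least 95 of 100 replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(100):
            dpsi = rng.normal(size=21) + 2.0
            dsal = rng.normal(size=21)
            hits += rm_anova(dpsi, dsal, _groups(15, 6))["treatment"].p_param < 0.01
        assert hits >= 95

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.zeros(3), np.ones(3), ("ADE", "ADE", "control"))


class TestPermutationAnova:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        dpsi, dsal = rng.normal(size=21), rng.normal(size=21)
        a = permutation_anova(dpsi, dsal, _groups(15, 6), n_perm=500, seed=9)
        b = permutation_anova(dpsi, dsal, _groups(15, 6), n_perm=500, seed=9)
        assert a["treatment"].p_perm == b["treatment"].p_perm
        assert a["interaction"].p_perm == b["interaction"].p_perm

    def test_agrees_with_parametric_on_gaussian_data(self):
        """For Gaussian errors the permutation p matches the parametric p
        closely (median absolute difference over replicates)."""
        rng = np.random.default_rng(5)
        diffs = []
        for k in range(100):
            dpsi = rng.normal(size=21) + 0.5
            dsal = rng.normal(size=21)
            res = permutation_anova(dpsi, dsal, _groups(15, 6),
                                    n_perm=10000, seed=k)
            diffs.append(abs(res["treatment"].p_perm - res["treatment"].p_param))
        assert np.median(diffs) <= 0.02

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="permutations"):
            permutation_anova(rng.normal(size=8), rng.normal(size=8),
                              _groups(4, 4), n_perm=50, seed=0)


class TestAssumptionChecks:
    def test_gaussian_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        n_sim = 500
        rej = sum(assumption_checks({"c": rng.normal(size=20)})[0]["c"] < 0.05
                  for _ in range(n_sim))
        lo, hi = sps.binom.interval(0.95, n_sim, 0.05)
        assert lo <= rej <= hi

    def test_bartlett_detects_variance_ratio_nine(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            cells = {"a": rng.normal(size=20), "b": rng.normal(scale=3.0, size=20)}
            hits += assumption_checks(cells)[1] < 0.05
        assert hits >= 90

    def test_constant_cell_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            assumption_checks({"a": np.ones(5), "b": np.arange(5.0)})


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_order_preserved(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=20)
        adj = fdr_adjust(p)
        assert (np.argsort(p) == np.argsort(adj, kind="stable")).all() or \
            (adj[np.argsort(p)] == np.sort(adj)).all()

    def test_family_size_padding(self):
        """Correcting 3 p-values within a family of 10 tests equals BH on the
        padded list: p * m / rank, monotonized."""
        p = [0.001, 0.01, 0.04]
        adj = fdr_adjust(p, m=10)
        np.testing.assert_allclose(adj, [0.01, 0.05, 0.04 * 10 / 3])
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 0.2], m=1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestSpearman:
    def test_monotone_map_gives_unity(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        assert spearman_rho(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 8.0, 8.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 7.0, 6.0, 5.0, 9.0, 9.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_exact_small_sample_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman_rho(x, y)
        null = []
        for perm in itertools.permutations(range(6)):
            null.append(sps.spearmanr(x, y[list(perm)]).statistic)
        expected = np.mean(np.abs(null) >= abs(res.rho) - 1e-12)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(5), np.arange(5.0))


class TestRhoToT:
    def test_zero_and_printed_example(self):
        assert rho_to_t(0.0, 15) == 0.0
        assert rho_to_t(0.57, 15) == pytest.approx(2.50, abs=0.01)
        assert rho_to_t(-0.57, 15) == pytest.approx(2.50, abs=0.01)

    def test_perfect_correlation_flagged_infinite(self):
        assert rho_to_t(1.0, 10) == np.inf

    def test_monotone_in_rho_and_n(self):
        ts = [rho_to_t(r, 12) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(ts, ts[1:]))
        ts_n = [rho_to_t(0.5, n) for n in (5, 10, 20, 40)]
        assert all(a < b for a, b in zip(ts_n, ts_n[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rho_to_t(0.5, 2)
        with pytest.raises(ValueError):
            rho_to_t(1.5, 10)


class TestCriticalThreshold:
    def test_median_of_t_is_zero(self):
        assert critical_threshold(0.5, 20, "t") == 0.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            critical_threshold(0.0, 20, "t")


class TestClusterCorrect:
    def test_subthreshold_map_has_no_clusters(self):
        rng = np.random.default_rng(11)
        maps = rng.normal(size=(12, 5, 5, 3), scale=0.1)
        mask = np.ones((5, 5, 3), dtype=bool)
        res = cluster_correct(maps, mask, cdt=50.0, n_perm=100, seed=0)
        assert res.clusters == []

    def test_planted_block_detected(self):
        rng = np.random.default_rng(12)
        maps = rng.normal(size=(14, 6, 6, 4))
        maps[:, 1:4, 1:4, 1:3] += 3.0
        mask = np.ones((6, 6, 4), dtype=bool)
        res = cluster_correct(maps, mask, cdt=2.65, n_perm=300, seed=1)
        assert res.clusters
        assert res.clusters[0].p_fwe <= 0.05
        assert res.clusters[0].extent >= 10

    def test_correlation_mode_detects_covariate_cluster(self):
        rng = np.random.default_rng(13)
        n = 15
        cov = rng.uniform(100, 160, size=n)
        maps = rng.normal(size=(n, 6, 6, 2))
        maps[:, 0:3, 0:3, :] -= 0.05 * (cov - 130)[:, None, None, None]
        mask = np.ones((6, 6, 2), dtype=bool)
        res = cluster_correct(maps, mask, cdt=2.65, n_perm=300, seed=2,
                              covariate=cov)
        assert res.clusters and res.clusters[0].p_fwe <= 0.05

    def test_connectivity_must_be_valid(self):
        with pytest.raises(ValueError):
            cluster_correct(np.zeros((5, 3, 3, 3)), np.ones((3, 3, 3), bool),
                            cdt=2.0, connectivity=10)


class TestNormalizedRelapse:
    def test_equal_intakes_give_hundred_percent(self):
        assert normalized_relapse(5.0, 5.0) == pytest.approx(100.0)

    def test_group_mean_ratio(self):
        assert normalized_relapse(6.35, 8.10) == pytest.approx(127.6, abs=0.1)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalized_relapse(0.0, 5.0)
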