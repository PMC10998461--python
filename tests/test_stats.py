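"""Tests of the cohort statistics against enumeration oracles and
parameter-recovery simulations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flexms.stats import (
    covariate_model,
    fdr_adjust,
    fit_interaction_model,
    kfold_cv_predict,
    kruskal_wallis,
    residual_permutation_test,
    spearman,
    subgroup_correlations,
    wilcoxon_ranksum,
)
from flexms.synthetic import SyntheticCohortSpec, simulate_cohort


def exact_ranksum_p(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of C(n, n_a)
    group assignments (no ties)."""
    pooled = sorted(a) + sorted(b)
    n, n_a = len(pooled), len(a)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(n), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(sa, sb))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestRanksum:
    def test_hand_example(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        assert wilcoxon_ranksum([1.0, 2.5, 3.1], [1.0, 2.5, 3.1]).p_value == pytest.approx(1.0)

    def test_extreme_shift_attains_exact_minimum(self):
        a, b = [1, 2, 3, 4], [101, 102, 103, 104]
        res = wilcoxon_ranksum(a, b)
        assert res.p_value == pytest.approx(exact_ranksum_p(a, b), abs=1e-12)
        assert res.p_value == pytest.approx(2 / math.comb(8, 4), abs=1e-12)

    @given(
        a=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
        b=st.lists(st.integers(0, 1000), min_size=2, max_size=5),
    )
    def test_matches_enumeration_oracle(self, a, b):
        pooled = a + b
        if len(set(pooled)) < len(pooled):  # oracle assumes no ties
            return
        res = wilcoxon_ranksum(a, b)
        assert res.p_value == pytest.approx(exact_ranksum_p(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestKruskalWallis:
    def test_hand_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-9)

    def test_two_groups_reduce_to_ranksum_chi2(self):
        a, b = [1.0, 4.0, 2.5], [6.0, 8.0, 5.0, 9.0]
        h = kruskal_wallis([a, b]).statistic
        # H equals the squared standardized rank-sum statistic (no ties)
        from scipy.stats import ranksums
        z = ranksums(a, b).statistic
        assert h == pytest.approx(z * z, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05, 1.0], [0.10, 1.0]),
            ([0.5], [0.5]),
        ],
    )
    def test_hand_bh(self, p, expected):
        np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotone_and_bounded(self, p):
        adj = fdr_adjust(p)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 8.0, 9.0]).statistic == pytest.approx(1.0)
        assert spearman(x, [9.0, 8.0, 3.0, 2.0]).statistic == pytest.approx(-1.0)

    def test_hand_rho(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8, abs=1e-12)
        # exact enumeration: 8 of 24 permutations reach |rho| >= 0.8
        assert res.p_value == pytest.approx(8 / 24, abs=1e-12)

    def test_exact_vs_t_approximation_regimes(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        from scipy.stats import spearmanr
        res = spearman(x, y)
        ref = spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestInteractionModel:
    def test_vif_reported_for_nonintercept_terms(self):
        cohort = simulate_cohort(SyntheticCohortSpec(seed=31))
        fit = fit_interaction_model(cohort)
        assert set(fit.vif) == {"repertoire", "phenotype", "interaction"}
        assert all(v >= 1.0 for v in fit.vif.values())
        assert fit.df == (3, 21)

    def test_rejects_small_or_degenerate_cohorts(self):
        cohort = simulate_cohort(SyntheticCohortSpec(seed=32))
        tiny = cohort[cohort["group"] != "HC"].head(6)
        with pytest.raises(ValueError):
            fit_interaction_model(pd.concat([tiny]))
        lopsided = pd.concat([
            cohort[cohort["group"] == "RRMS"],
            cohort[cohort["group"] == "SPMS"].head(2),
        ])
        with pytest.raises(ValueError):
            fit_interaction_model(lopsided)

    def test_type_i_calibration_f_test(self):
        # response independent of predictors: F rejects at ~5%
        rng = np.random.default_rng(33)
        n_reps, hits = 400, 0
        base = simulate_cohort(SyntheticCohortSpec(n_per_group=40, seed=34))
        ms_mask = base["group"].isin(("RRMS", "SPMS"))
        for _ in range(n_reps):
            cohort = base.copy()
            cohort.loc[ms_mask, "edss"] = rng.normal(size=ms_mask.sum())
            hits += fit_interaction_model(cohort).f_p < 0.05
        assert hits / n_reps == pytest.approx(0.05, abs=0.03)


class TestKfoldCV:
    def test_noiseless_cohort_predicts_perfectly(self):
        cohort = simulate_cohort(SyntheticCohortSpec(noise_sd=0.0, seed=41))
        res = kfold_cv_predict(cohort, k=5, seed=0)
        assert res.nrmse <= 1e-6

    def test_same_seed_same_folds_and_predictions(self):
        cohort = simulate_cohort(SyntheticCohortSpec(seed=42))
        r1 = kfold_cv_predict(cohort, k=5, seed=9)
        r2 = kfold_cv_predict(cohort, k=5, seed=9)
        np.testing.assert_array_equal(r1.cv_predictions, r2.cv_predictions)
        assert r1.nrmse == r2.nrmse

    def test_pure_noise_predictions_uncorrelated(self):
        rng = np.random.default_rng(43)
        rs = []
        base = simulate_cohort(SyntheticCohortSpec(n_per_group=30, seed=44))
        ms_mask = base["group"].isin(("RRMS", "SPMS"))
        for rep in range(40):
            cohort = base.copy()
            cohort.loc[ms_mask, "edss"] = rng.normal(size=ms_mask.sum())
            res = kfold_cv_predict(cohort, k=5, seed=rep)
            rs.append(np.corrcoef(res.cv_predictions, res.cv_actual)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_training_folds_ignore_test_fold_outlier(self):
        cohort = simulate_cohort(SyntheticCohortSpec(seed=45))
        res = kfold_cv_predict(cohort, k=5, seed=1)
        ms = cohort[cohort["group"].isin(("RRMS", "SPMS"))].reset_index(drop=True)
        # plant an extreme outlier in one subject; only that subject's own
        # prediction (made by models that never saw it) may change, plus
        # nothing else if standardization is computed on training folds only
        target = ms.loc[0, "subject_id"]
        spiked = cohort.copy()
        spiked.loc[spiked["subject_id"] == target, "repertoire_size"] = 10_000
        res2 = kfold_cv_predict(spiked, k=5, seed=1)
        rng = np.random.default_rng(1)
        order = rng.permutation(len(ms))
        folds = np.array_split(order, 5)
        outlier_fold = next(f for f in folds if 0 in f)
        # the model predicting the outlier's fold is fit without that fold,
        # so the outlier cannot leak into its fold-mates' predictions (its
        # own prediction changes because its feature changed)
        fold_mates = [i for i in outlier_fold.tolist() if i != 0]
        np.testing.assert_array_equal(res.cv_predictions[fold_mates],
                                      res2.cv_predictions[fold_mates])
        changed = np.flatnonzero(res.cv_predictions != res2.cv_predictions)
        assert 0 in changed  # sanity: the spike did flow through its features

    def test_k_out_of_range_rejected(self):
        cohort = simulate_cohort(SyntheticCohortSpec(seed=46))
        with pytest.raises(ValueError):
            kfold_cv_predict(cohort, k=26)


class TestResidualPermutation:
    def test_identical_groups_p_one(self):
        res = residual_permutation_test([2.0, 2.0, -2.0, -2.0], ["a", "a", "b", "b"],
                                        n_iterations=500, seed=0)
        assert res.observed_stat == 0.0 and res.p_value == 1.0

    def test_extreme_separation_matches_enumeration(self):
        # groups [0,0,0] vs [9,9,9]: only 2 of C(6,3)=20 label splits
        # reach |diff| = 9, so the exact p is 0.1
        res = residual_permutation_test([0, 0, 0, 9, 9, 9], [0, 0, 0, 1, 1, 1],
                                        n_iterations=10_000, seed=5)
        mc_sd = math.sqrt(0.1 * 0.9 / 10_000)
        assert abs(res.p_value - 0.1) < 3 * mc_sd + 2e-4

    def test_seed_determinism_and_p_bounds(self):
        resid = np.random.default_rng(7).normal(size=20)
        labels = [0] * 10 + [1] * 10
        r1 = residual_permutation_test(resid, labels, n_iterations=1000, seed=3)
        r2 = residual_permutation_test(resid, labels, n_iterations=1000, seed=3)
        assert r1.p_value == r2.p_value
        assert 1 / 1001 <= r1.p_value <= 1.0

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            residual_permutation_test([1, 2, 3], ["a", "a", "a"])


class TestCovariateModel:
    def make_cohort(self, rng, n=120):
        cohort = simulate_cohort(SyntheticCohortSpec(n_per_group=n // 3, seed=51))
        cohort["age"] = rng.normal(45, 10, size=len(cohort))
        cohort["sex"] = rng.choice(["M", "F"], size=len(cohort))
        cohort["education"] = rng.normal(13, 4, size=len(cohort))
        cohort["roi_volume"] = rng.normal(600, 80, size=len(cohort))
        return cohort

    def test_exact_recovery_without_noise(self, rng):
        cohort = self.make_cohort(rng)
        cohort["repertoire_size"] = 2.0 * cohort["roi_volume"]
        table = covariate_model(cohort, variables=["roi_volume"])
        assert table.loc[0, "beta"] == pytest.approx(2.0, rel=1e-8)

    def test_covariate_only_response_gives_null_variable(self, rng):
        cohort = self.make_cohort(rng)
        cohort["repertoire_size"] = 3.0 * cohort["age"] + rng.normal(0, 1, len(cohort))
        table = covariate_model(cohort, variables=["roi_volume"])
        assert not table.loc[0, "significant"]

    def test_fdr_across_variable_family(self, rng):
        cohort = self.make_cohort(rng)
        for i in range(4):
            cohort[f"vol_{i}"] = rng.normal(size=len(cohort))
        table = covariate_model(cohort, variables=[f"vol_{i}" for i in range(4)])
        assert (table["p_fdr"] >= table["p"] - 1e-12).all()

    def test_constant_covariate_rejected(self, rng):
        cohort = self.make_cohort(rng)
        cohort["education"] = 13.0
        with pytest.raises(ValueError, match="education"):
            covariate_model(cohort, variables=["roi_volume"])

    def test_missing_column_rejected(self, rng):
        cohort = self.make_cohort(rng)
        with pytest.raises(ValueError, match="lesion_load"):
            covariate_model(cohort, variables=["lesion_load"])


class TestSubgroupCorrelations:
    def make_cohort(self, n=60, seed=61):
        # positive repertoire-EDSS slope in RRMS only
        spec = SyntheticCohortSpec(
            n_per_group=n, beta_repertoire=0.05, beta_interaction=-0.05,
            noise_sd=0.3, seed=seed,
        )
        return simulate_cohort(spec)

    def test_phenotype_split_detects_group_specific_slope(self):
        table = subgroup_correlations(self.make_cohort(), "phenotype", "edss")
        rrms = table[table["subgroup"] == "RRMS"].iloc[0]
        spms = table[table["subgroup"] == "SPMS"].iloc[0]
        assert rrms["rho"] > 0.5 and rrms["p"] < 0.01
        assert abs(spms["rho"]) < 0.3

    def test_cutoff_above_all_flags_empty_subgroup(self):
        table = subgroup_correlations(self.make_cohort(), "edss_cutoff:99", "edss")
        high = table[table["subgroup"] == "edss>99"].iloc[0]
        assert high["n"] == 0 and high["note"] == "insufficient n"

    def test_median_split_near_equal_sizes(self):
        table = subgroup_correlations(self.make_cohort(), "edss_median", "edss")
        sizes = table["n"].to_numpy()
        assert abs(sizes[0] - sizes[1]) <= 0.2 * sizes.sum()

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            subgroup_correlations(self.make_cohort(), "bogus")
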