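"""Cohort statistics: ANCOVA, demographics, partial correlation, normality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nmseg.cohort import CohortSpec, GroupSpec, simulate_cohort
from nmseg.stats import (ancova, chisq_from_counts, demographics_anova,
                         demographics_chisq, normality_check,
                         partial_correlation)


def _two_group_spec(mean_a=350.0, mean_b=350.0, n=30, sd=100.0):
    return CohortSpec(groups=[GroupSpec("a", n, mean_a, sd),
                              GroupSpec("b", n, mean_b, sd)])


class TestAncova:
    def test_reduces_to_one_way_anova_without_covariates(self):
        t = simulate_cohort(_two_group_spec(360, 320), seed=0)
        res = ancova(t, covariates=[])
        F, p = demographics_anova(t, "snc_volume")
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.p == pytest.approx(p, abs=1e-8)

    def test_constructed_confound_loads_on_covariate_not_group(self):
        rng = np.random.default_rng(0)
        age = rng.normal(60, 10, 80)
        t = pd.DataFrame({"group": ["a"] * 40 + ["b"] * 40, "age": age,
                          "snc_volume": 10.0 * age})
        res = ancova(t, covariates=["age"])
        assert res.F == pytest.approx(0.0, abs=1e-6)
        assert res.covariate_tests["age"][1] < 1e-10

    def test_outcome_shift_moves_means_not_f(self):
        t = simulate_cohort(_two_group_spec(360, 320), seed=1)
        res1 = ancova(t)
        t2 = t.assign(snc_volume=t.snc_volume + 100.0)
        res2 = ancova(t2)
        assert res2.F == pytest.approx(res1.F, rel=1e-10)
        assert res2.p == pytest.approx(res1.p, rel=1e-10)
        for g in res1.marginal_means:
            assert res2.marginal_means[g][0] - res1.marginal_means[g][0] == \
                pytest.approx(100.0, abs=1e-8)

    def test_balanced_covariates_give_raw_group_means(self):
        # With covariates identical across groups the adjusted means are the
        # raw group means.
        n = 20
        t = pd.DataFrame({
            "group": ["a"] * n + ["b"] * n,
            "age": list(range(n)) * 2,
            "sex": (["M", "F"] * (n // 2)) * 2,
            "snc_volume": [300.0] * n + [400.0] * n,
        })
        res = ancova(t, covariates=["age", "sex"])
        assert res.marginal_means["a"][0] == pytest.approx(300.0, abs=1e-8)
        assert res.marginal_means["b"][0] == pytest.approx(400.0, abs=1e-8)

    def test_rank_deficiency_names_aliased_columns(self):
        t = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                          "site": ["s1"] * 10 + ["s2"] * 10,
                          "snc_volume": np.random.default_rng(0).normal(350, 50, 20)})
        with pytest.raises(ValueError, match="aliased"):
            ancova(t, covariates=["site"])

    def test_group_effect_parameter_recovery(self):
        # A -60 mm^3 simulated deficit is recovered in the marginal-mean
        # difference within 2 SEs in nearly all replicates.
        hits = 0
        reps = 100
        for rep in range(reps):
            spec = CohortSpec(groups=[GroupSpec("a", 60, 390.0, 100.0),
                                      GroupSpec("b", 60, 330.0, 100.0)])
            t = simulate_cohort(spec, seed=rep)
            res = ancova(t)
            (ma, sa), (mb, sb) = res.marginal_means["a"], res.marginal_means["b"]
            diff, se = ma - mb, np.hypot(sa, sb)
            hits += abs(diff - 60.0) <= 2 * se
        assert hits / reps >= 0.93

    def test_posthoc_pairs_and_correction_flag(self):
        spec = CohortSpec(groups=[GroupSpec("a", 30, 400.0, 80.0),
                                  GroupSpec("b", 30, 330.0, 80.0),
                                  GroupSpec("c", 30, 320.0, 80.0)])
        t = simulate_cohort(spec, seed=2)
        res = ancova(t)
        assert len(res.posthoc) == 3
        res_bonf = ancova(t, posthoc_correction="bonferroni")
        for pair in res.posthoc:
            assert res_bonf.posthoc[pair] >= res.posthoc[pair] - 1e-12

    def test_missing_rows_are_dropped_listwise(self):
        t = simulate_cohort(_two_group_spec(), seed=3)
        t.loc[t.index[:5], "age"] = np.nan
        res = ancova(t)
        assert res.n_dropped == 5
        assert res.n_used == len(t) - 5

    def test_too_small_groups_rejected(self):
        t = pd.DataFrame({"group": ["a", "a", "b"], "snc_volume": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="n >= 2"):
            ancova(t, covariates=[])


class TestDemographics:
    def test_null_pvalues_are_uniform(self):
        # Permuted labels over one pooled sample: ANOVA p-values ~ U(0,1).
        rng = np.random.default_rng(0)
        values = rng.normal(60, 10, 60)
        ps = []
        for _ in range(1000):
            labels = rng.permutation(["a"] * 30 + ["b"] * 30)
            t = pd.DataFrame({"group": labels, "age": values})
            ps.append(demographics_anova(t, "age")[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_independent_2x2_table(self):
        chi2, p = chisq_from_counts([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_published_sex_table_reproduces_chi_square(self):
        # Control [31 M / 19 F] vs LRRK2 non-manifest carriers [19 M / 27 F].
        chi2, p = chisq_from_counts([[31, 19], [19, 27]])
        assert chi2 == pytest.approx(4.11, abs=0.005)
        assert p == pytest.approx(0.043, abs=0.0005)

    def test_zero_expected_cell_is_an_error(self):
        with pytest.raises(ValueError):
            chisq_from_counts([[5, 0], [7, 0]])

    def test_chisq_from_table_columns(self):
        t = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4,
                          "sex": ["M", "M", "F", "F"] * 2})
        chi2, p = demographics_chisq(t, "sex")
        assert chi2 == 0.0 and p == 1.0


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        t = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)})
        r, p = partial_correlation(t, "x", "y")
        r_ref, p_ref = sps.pearsonr(t.x, t.y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_variables_give_unit_correlation(self, rng):
        x = rng.normal(size=30)
        t = pd.DataFrame({"x": x, "y": x, "age": rng.normal(size=30)})
        r, _ = partial_correlation(t, "x", "y", ["age"])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_residual_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 50
            t = pd.DataFrame({
                "x": rng.normal(size=n), "y": rng.normal(size=n),
                "age": rng.normal(60, 8, n),
                "tbv": rng.normal(1.1e6, 1e5, n),
            })
            r, _ = partial_correlation(t, "x", "y", ["age", "tbv"])
            Z = np.column_stack([np.ones(n), t.age, t.tbv])
            rx = t.x - Z @ np.linalg.lstsq(Z, t.x, rcond=None)[0]
            ry = t.y - Z @ np.linalg.lstsq(Z, t.y, rcond=None)[0]
            r_oracle = np.corrcoef(rx, ry)[0, 1]
            assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_after_residualisation_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                          "y": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
                          "z": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(t, "x", "y", ["z"])

    def test_insufficient_rows_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 1.0], "z": [1.0, 5.0]})
        with pytest.raises(ValueError, match="rows"):
            partial_correlation(t, "x", "y", ["z"])


class TestNormalityCheck:
    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 500
        for _ in range(reps):
            t = pd.DataFrame({"group": "g", "snc_volume": rng.normal(350, 100, 200)})
            _, p = normality_check(t)["g"]
            rejections += p < 0.05
        rate = rejections / reps
        tol = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= tol

    def test_skewed_sample_is_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(50):
            t = pd.DataFrame({"group": "g", "snc_volume": rng.exponential(100, 200)})
            hits += normality_check(t)["g"][1] < 0.05
        assert hits / 50 >= 0.95

    def test_constant_sample_is_an_error(self):
        t = pd.DataFrame({"group": "g", "snc_volume": [5.0] * 10})
        with pytest.raises(ValueError, match="constant"):
            normality_check(t)

    def test_small_group_is_an_error(self):
        t = pd.DataFrame({"group": "g", "snc_volume": [1.0, 2.0]})
        with pytest.raises(ValueError, match="n >= 3"):
            normality_check(t)
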