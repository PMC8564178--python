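"""Between-group inference: chi-square, ANOVA, permutation ANCOVA, partials."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocouple.group_stats import (
    ancova_permutation,
    chi_square_test,
    demographics_table,
    kruskal_wallis,
    oneway_anova,
    oneway_anova_summary,
    partial_correlation,
    regionwise_ancova,
    zscore_cognition,
)
from neurocouple.types import ValidationError


def _three_groups(rng, sizes=(32, 24, 30)):
    groups = np.repeat(["mild", "moderate", "severe"], sizes)
    n = groups.size
    covar = np.column_stack([rng.normal(64, 6, n), rng.integers(0, 2, n).astype(float)])
    return groups, covar, n


class TestZscoreCognition:
    def test_mean_zero_unit_sd(self, rng):
        raw = pd.DataFrame({"mmse": rng.normal(27, 2, 40), "avlt": rng.normal(6, 2, 40)})
        z = zscore_cognition(raw)
        for col in z:
            assert z[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[col].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_timed_tests_flipped(self, rng):
        raw = pd.DataFrame({"tmt_a": rng.normal(55, 15, 40), "mmse": rng.normal(27, 2, 40)})
        z = zscore_cognition(raw)
        # longer time (worse) must map to lower z
        assert np.corrcoef(raw["tmt_a"], z["tmt_a"])[0, 1] == pytest.approx(-1.0)
        assert np.corrcoef(raw["mmse"], z["mmse"])[0, 1] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            zscore_cognition(pd.DataFrame({"mmse": [27.0, 27.0, 27.0]}))


class TestBasicTests:
    def test_chi_square_hand_value(self):
        # 2x2 table [[10,20],[20,10]]: chi2 = 60*(10*10-20*20)^2/(30*30*30*30)
        table = np.array([[10, 20], [20, 10]])
        chi2, dof, p = chi_square_test(table)
        expected = 60 * (10 * 10 - 20 * 20) ** 2 / (30 * 30 * 30 * 30)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert dof == 1
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_chi_square_empty_column(self):
        with pytest.raises(ValidationError):
            chi_square_test(np.array([[5, 0], [3, 0]]))

    def test_anova_hand_value(self):
        # groups {1,2,3}, {2,3,4}, {4,5,6}: grand mean (6+9+15)/9 = 10/3
        vals = np.array([1, 2, 3, 2, 3, 4, 4, 5, 6], dtype=float)
        grp = np.repeat(["a", "b", "c"], 3)
        f, df1, df2, p = oneway_anova(vals, grp)
        ss_between = 3 * ((2 - 10 / 3) ** 2 + (3 - 10 / 3) ** 2 + (5 - 10 / 3) ** 2)
        ss_within = 6 * 1.0  # each group has variance 1 with df 2
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert f == pytest.approx(f_hand, rel=1e-12)
        assert (df1, df2) == (2, 6)

    def test_anova_summary_matches_raw(self, rng):
        grp = np.repeat(["a", "b", "c"], (12, 9, 11))
        vals = rng.normal(0, 1, grp.size) + (grp == "c") * 0.8
        f_raw, _, _, p_raw = oneway_anova(vals, grp)
        ns = np.array([12, 9, 11])
        means = [vals[grp == g].mean() for g in ["a", "b", "c"]]
        sds = [vals[grp == g].std(ddof=1) for g in ["a", "b", "c"]]
        f_sum, p_sum = oneway_anova_summary(ns, means, sds)
        assert f_sum == pytest.approx(f_raw, rel=1e-10)
        assert p_sum == pytest.approx(p_raw, rel=1e-10)

    def test_kruskal_matches_scipy(self, rng):
        vals = rng.normal(size=30)
        grp = np.repeat(["a", "b", "c"], 10)
        h, p = kruskal_wallis(vals, grp)
        h2, p2 = stats.kruskal(vals[:10], vals[10:20], vals[20:])
        assert h == pytest.approx(h2) and p == pytest.approx(p2)


class TestAncovaPermutation:
    def test_no_covariates_f_equals_oneway(self, rng):
        groups, _, n = _three_groups(rng)
        y = rng.normal(size=n)
        res = ancova_permutation(y, groups, None, n_perm=200, seed=1)
        f_anova, *_ = oneway_anova(y, groups)
        assert res.f_obs == pytest.approx(f_anova, rel=1e-10)

    def test_strong_effect_detected_with_posthoc(self, rng):
        groups, covar, n = _three_groups(rng)
        y = rng.normal(size=n) + 2.0 * (groups == "severe")
        res = ancova_permutation(y, groups, covar, n_perm=500, alpha=0.01, seed=2)
        assert res.p_perm < 0.01
        assert len(res.posthoc) == 3
        t_ms = res.posthoc[("mild", "severe")]
        assert t_ms["direction"] > 0  # severe coded second, higher mean

    def test_null_not_significant_no_posthoc(self, rng):
        groups, covar, n = _three_groups(rng)
        y = rng.normal(size=n)
        res = ancova_permutation(y, groups, covar, n_perm=500, alpha=0.01, seed=3)
        assert res.p_perm > 0.01
        assert res.posthoc == {}

    def test_add_one_floor(self, rng):
        groups, covar, n = _three_groups(rng)
        y = 5.0 * (groups == "severe") + 0.01 * rng.normal(size=n)
        res = ancova_permutation(y, groups, covar, n_perm=199, posthoc=False, seed=4)
        assert res.p_perm >= 1.0 / 200.0
        assert res.p_perm == pytest.approx(1.0 / 200.0)

    def test_covariate_confound_controlled(self, rng):
        # outcome driven purely by age, and age differs by group:
        # the covariate-adjusted test must not call the group significant
        groups, _, n = _three_groups(rng)
        age = rng.normal(64, 5, n) + 4.0 * (groups == "severe")
        y = 0.5 * age + rng.normal(0, 0.5, n)
        res = ancova_permutation(y, groups, age[:, None], n_perm=500, seed=5)
        naive = ancova_permutation(y, groups, None, n_perm=500, seed=5, posthoc=False)
        assert naive.p_perm < 0.01  # unadjusted picks up the confound
        assert res.p_perm > 0.01

    def test_labels_scheme_runs(self, rng):
        groups, covar, n = _three_groups(rng)
        y = rng.normal(size=n)
        res = ancova_permutation(y, groups, covar, n_perm=200, seed=6, scheme="labels")
        assert 0 < res.p_perm <= 1

    def test_bad_scheme(self, rng):
        groups, covar, n = _three_groups(rng)
        with pytest.raises(ValidationError, match="scheme"):
            ancova_permutation(rng.normal(size=n), groups, covar, scheme="parametric")


class TestRegionwiseAncova:
    def test_one_row_per_region_and_fdr(self, rng):
        groups, covar, n = _three_groups(rng)
        values = pd.DataFrame(
            {f"r{j}": rng.normal(size=n) for j in range(6)}
        )
        values["r0"] += 2.0 * (groups == "severe")
        out = regionwise_ancova(values, groups, covar, n_perm=300, seed=7, fdr=True)
        assert len(out) == 6
        assert set(out["region_id"]) == set(values.columns)
        assert (out["p_fdr"] >= out["p_perm"] - 1e-12).all()
        assert bool(out.loc[out["region_id"] == "r0", "significant"].iloc[0])

    def test_reproducible_given_seed(self, rng):
        groups, covar, n = _three_groups(rng)
        values = pd.DataFrame({f"r{j}": rng.normal(size=n) for j in range(3)})
        a = regionwise_ancova(values, groups, covar, n_perm=200, seed=11)
        b = regionwise_ancova(values, groups, covar, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestPartialCorrelation:
    def test_no_covariates_matches_pearson(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        r, p = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_confounder_removed(self, rng):
        c = rng.normal(size=200)
        x = c + 0.1 * rng.normal(size=200)
        y = c + 0.1 * rng.normal(size=200)
        r_raw, _ = partial_correlation(x, y)
        r_adj, p_adj = partial_correlation(x, y, c[:, None])
        assert r_raw > 0.9
        assert abs(r_adj) < 0.2

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValidationError):
            partial_correlation(rng.normal(size=4), rng.normal(size=4), rng.normal(size=(4, 2)))


class TestDemographicsTable:
    def test_structure_and_pvalues(self, rng):
        n = 60
        frame = pd.DataFrame(
            {
                "group": np.repeat(["mild", "moderate", "severe"], 20),
                "age": rng.normal(64, 5, n),
                "education_years": rng.normal(11, 3, n),
                "sex": rng.choice(["M", "F"], n),
                "hypertension": rng.integers(0, 2, n).astype(bool),
                "diabetes": rng.integers(0, 2, n).astype(bool),
                "smoking": rng.integers(0, 2, n).astype(bool),
                "drinking": rng.integers(0, 2, n).astype(bool),
            }
        )
        table = demographics_table(frame)
        assert list(table.columns) == ["variable", "mild", "moderate", "severe", "test", "p"]
        assert table["p"].between(0, 1).all()
        assert (table.loc[table["variable"] == "age", "test"] == "Kruskal-Wallis").all()
        assert (table.loc[table["variable"] == "sex", "test"] == "chi-square").all()
        # chi-square row agrees with an independent scipy computation
        tab = pd.crosstab(frame["group"], frame["sex"]).loc[["mild", "moderate", "severe"]]
        ref_p = stats.chi2_contingency(tab.to_numpy(), correction=False)[1]
        assert table.loc[table["variable"] == "sex", "p"].iloc[0] == pytest.approx(ref_p)
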