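"""Hierarchical models, group comparisons, stratified slopes, ANCOVA, APOE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbiprs import association as assoc
from tbiprs.synthetic_cohort import (
    CohortDesign,
    SyntheticTruth,
    simulate_cohort_phenotypes,
    simulate_genotype_panel,
    simulate_summary_stats,
    true_prs,
)


def _pheno_frame(n, rng, tbi=None, severity=None, e4=None, ratio=None):
    """Minimal raw phenotype table for unit-level checks."""
    tbi = np.asarray(tbi if tbi is not None else rng.integers(0, 2, n))
    if severity is None:
        severity = np.where(tbi == 1, "mild", "none")
    ab40 = np.full(n, 10_000.0)
    ratio = np.asarray(ratio if ratio is not None else rng.normal(0.09, 0.01, n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.normal(68, 3, n),
            "education_yrs": rng.normal(15, 2, n),
            "caps_total": rng.uniform(0, 100, n),
            "tbi": tbi,
            "tbi_severity": severity,
            "apoe_e4_count": e4 if e4 is not None else rng.integers(0, 2, n),
            "abeta42_pg_ml": ratio * ab40,
            "abeta40_pg_ml": ab40,
        }
    )


class TestRatio:
    def test_ratio_arithmetic(self):
        rng = np.random.default_rng(0)
        t = _pheno_frame(5, rng)
        t.loc[0, ["abeta42_pg_ml", "abeta40_pg_ml"]] = (1000.0, 10_000.0)
        out = assoc.compute_ratio_and_standardize(t)
        assert out.loc[0, "abeta_ratio"] == pytest.approx(0.1)
        assert out["abeta_ratio_std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["abeta_ratio_std"].std(ddof=1) == pytest.approx(1.0)

    def test_equal_ratios_equal_z(self):
        rng = np.random.default_rng(1)
        t = _pheno_frame(4, rng, ratio=np.array([0.08, 0.1, 0.1, 0.12]))
        out = assoc.compute_ratio_and_standardize(t)
        assert out.loc[1, "abeta_ratio_std"] == pytest.approx(out.loc[2, "abeta_ratio_std"])

    def test_nonpositive_analyte_rejected(self):
        rng = np.random.default_rng(2)
        t = _pheno_frame(3, rng)
        t.loc[0, "abeta40_pg_ml"] = 0.0
        with pytest.raises(ValueError):
            assoc.compute_ratio_and_standardize(t)

    def test_assay_flags_attached(self):
        rng = np.random.default_rng(3)
        t = _pheno_frame(2, rng)
        t.loc[0, ["abeta42_pg_ml", "abeta40_pg_ml"]] = (1800.0, 20_000.0)
        out = assoc.compute_ratio_and_standardize(t)
        assert out.loc[0, "assay_flags"] == "ab42_above_1700"
        assert out.loc[1, "assay_flags"] == ""


@pytest.fixture(scope="module")
def big_cohort():
    """n = 5000 cohort with the planted -0.45 interaction, for recovery."""
    d, panel = simulate_genotype_panel(
        5000, 200, block_size=20, ld_rho=0.5, maf_range=(0.1, 0.5),
        dosage_noise_sd=0.05, missing_fraction=0.005, seed=31,
    )
    _, truth = simulate_summary_stats(panel, prop_causal=0.2, seed=31)
    design = CohortDesign(
        n_no_tbi=2000, n_mild=1500, n_moderate_severe=1500, n_indeterminate=0
    )
    ph = simulate_cohort_phenotypes(d, truth, design, seed=31)
    table = assoc.compute_ratio_and_standardize(ph)
    return table, true_prs(d, truth).to_numpy(), truth, d, panel


class TestHierarchicalModels:
    def test_nested_r2_and_constant_n(self, cohort):
        table = cohort["table"]
        prs_std = cohort["prs_full"].standardized.iloc[:, -1].to_numpy()
        fits = assoc.fit_hierarchical_models(table, prs_std)
        assert fits["model1"].r_squared <= fits["model2"].r_squared <= fits["model3"].r_squared
        assert len({f.n_used for f in fits.values()}) == 1
        terms = [set(f.coefficients.index) for f in fits.values()]
        assert terms[0] < terms[1] < terms[2]

    def test_partial_f_identity(self, cohort):
        table = cohort["table"]
        prs_std = cohort["prs_full"].standardized.iloc[:, -1].to_numpy()
        fits = assoc.fit_hierarchical_models(table, prs_std)
        F, p = assoc.partial_f(fits["model2"], fits["model3"])
        # adding one term: partial F equals the squared t of that term
        trow = fits["model3"].term("tbi:prs")
        np.testing.assert_allclose(F, (trow["B"] / trow["SE"]) ** 2, rtol=1e-10)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(4)
        t = assoc.compute_ratio_and_standardize(_pheno_frame(30, rng))
        prs_std = t["age"].to_numpy()  # aliased with the age covariate
        with pytest.raises(ValueError, match="collinear|aliased"):
            assoc.fit_hierarchical_models(t, prs_std)

    def test_interaction_recovery(self, big_cohort):
        table, prs_std, truth, *_ = big_cohort
        fits = assoc.fit_hierarchical_models(table, prs_std)
        b = fits["model3"].term("tbi:prs")["B"]
        assert b == pytest.approx(truth.effect_interaction, abs=0.05)

    def test_ols_matches_normal_equations(self):
        """Textbook oracle on a 10-row design, 1e-10 agreement."""
        rng = np.random.default_rng(5)
        t = assoc.compute_ratio_and_standardize(_pheno_frame(10, rng))
        prs_std = rng.normal(size=10)
        fits = assoc.fit_hierarchical_models(t, prs_std)
        df = pd.DataFrame(
            {
                "Intercept": 1.0,
                "age": t["age"],
                "education": t["education_yrs"],
                "caps": t["caps_total"],
                "tbi": t["tbi"].astype(float),
                "prs": prs_std,
            }
        )
        df["tbi:prs"] = df["tbi"] * df["prs"]
        X = df.to_numpy()
        y = t["abeta_ratio_std"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (10 - 7)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        got = fits["model3"].coefficients
        np.testing.assert_allclose(got["B"].to_numpy(), beta, atol=1e-10)
        np.testing.assert_allclose(got["SE"].to_numpy(), se, atol=1e-10)


class TestGroupComparisons:
    def test_fisher_cross_product_or(self):
        """2x2 counts 30/9 vs 35/13 give OR = 1.24 (2 dp)."""
        rng = np.random.default_rng(6)
        e4 = np.array([0] * 30 + [1] * 9 + [0] * 35 + [1] * 13)
        tbi = np.array([0] * 39 + [1] * 48)
        t = assoc.compute_ratio_and_standardize(_pheno_frame(87, rng, tbi=tbi, e4=e4))
        res = assoc.group_comparisons(t)["apoe_carrier"]
        assert round(res.odds_ratio, 2) == 1.24
        assert res.table == ((30, 9), (35, 13))
        assert res.p == pytest.approx(stats.fisher_exact([[30, 9], [35, 13]])[1])

    def test_missing_e4_dropped_from_fisher_only(self):
        rng = np.random.default_rng(7)
        e4 = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, np.nan])
        t = _pheno_frame(10, rng, tbi=np.array([0] * 5 + [1] * 5), e4=e4)
        t = assoc.compute_ratio_and_standardize(t)
        res = assoc.group_comparisons(t)
        assert res["apoe_carrier"].n_used == 9
        assert res["age"].df > 0  # t-tests still use all rows

    def test_welch_matches_scipy_and_fractional_df(self):
        rng = np.random.default_rng(8)
        tbi = np.array([0] * 20 + [1] * 25)
        t = assoc.compute_ratio_and_standardize(_pheno_frame(45, rng, tbi=tbi))
        res = assoc.group_comparisons(t)["age"]
        a = t.loc[t["tbi"] == 0, "age"]
        b = t.loc[t["tbi"] == 1, "age"]
        sp = stats.ttest_ind(a, b, equal_var=False)
        np.testing.assert_allclose(res.t, sp.statistic, atol=1e-10)
        np.testing.assert_allclose(res.p, sp.pvalue, atol=1e-10)
        assert abs(res.df - round(res.df)) > 1e-6  # Welch df is fractional here

    def test_identical_groups(self):
        rng = np.random.default_rng(9)
        base = rng.normal(68, 3, 10)
        t = _pheno_frame(20, rng, tbi=np.array([0] * 10 + [1] * 10))
        t["age"] = np.concatenate([base, base])
        t = assoc.compute_ratio_and_standardize(t)
        res = assoc.group_comparisons(t)["age"]
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)


class TestStratified:
    def test_perfect_linear_gives_unit_partial_r(self):
        rng = np.random.default_rng(10)
        n = 30
        prs_std = rng.normal(size=n)
        t = _pheno_frame(n, rng, tbi=np.ones(n, dtype=int))
        t = assoc.compute_ratio_and_standardize(t)
        t["abeta_ratio_std"] = -2.0 * prs_std  # outcome exactly linear in PRS
        res = assoc.stratified_prs_effect(t, prs_std, group=True)
        assert res.partial_r == pytest.approx(-1.0)

    def test_partial_r_identity(self, cohort):
        table = cohort["table"]
        prs_std = cohort["prs_full"].standardized.iloc[:, -1].to_numpy()
        res = assoc.stratified_prs_effect(table, prs_std, group=True)
        tt = res.B / res.se
        df = res.n - 5
        assert res.partial_r**2 == pytest.approx(tt**2 / (tt**2 + df), rel=1e-10)

    def test_stratum_slopes_recover_planted_algebra(self, big_cohort):
        table, prs_std, truth, *_ = big_cohort
        tbi_slope = assoc.stratified_prs_effect(table, prs_std, group=True)
        no_slope = assoc.stratified_prs_effect(table, prs_std, group=False)
        assert no_slope.B == pytest.approx(truth.effect_prs, abs=0.05)
        assert tbi_slope.B == pytest.approx(
            truth.effect_prs + truth.effect_interaction, abs=0.05
        )

    def test_small_stratum_error(self):
        rng = np.random.default_rng(11)
        t = assoc.compute_ratio_and_standardize(
            _pheno_frame(8, rng, tbi=np.array([1, 1, 1, 0, 0, 0, 0, 0]))
        )
        with pytest.raises(ValueError):
            assoc.stratified_prs_effect(t, rng.normal(size=8), group=True)

    def test_interaction_equals_slope_difference_without_covariates(self):
        """Saturated two-stratum identity, exact on a covariate-free design."""
        rng = np.random.default_rng(12)
        n = 40
        tbi = np.array([0] * 20 + [1] * 20, dtype=float)
        prs = rng.normal(size=n)
        y = 0.3 * prs - 0.6 * tbi * prs + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "tbi": tbi, "prs": prs})
        full = assoc._ols(y, assoc._design(df, ["tbi", "prs", "tbi:prs"]), "full")
        s0 = np.polyfit(prs[tbi == 0], y[tbi == 0], 1)[0]
        s1 = np.polyfit(prs[tbi == 1], y[tbi == 1], 1)[0]
        assert full.term("tbi:prs")["B"] == pytest.approx(s1 - s0, abs=1e-10)


class TestSeverityAncova:
    def test_numerator_df_is_two(self, cohort):
        table = cohort["table"]
        prs_std = cohort["prs_full"].standardized.iloc[:, -1].to_numpy()
        res = assoc.severity_ancova(table, prs_std)
        assert res.interaction_df[0] == 2
        assert set(res.cell_slopes) == {"none", "mild", "moderate_severe"}

    def test_indeterminate_excluded(self, cohort):
        table = cohort["table"]
        prs_std = cohort["prs_full"].standardized.iloc[:, -1].to_numpy()
        res = assoc.severity_ancova(table, prs_std)
        n_indet = (table["tbi_severity"] == "indeterminate").sum()
        assert res.n_used == len(table) - n_indet

    def test_dose_response_ordering(self, big_cohort):
        """Steeper planted interaction with severity shows in the slopes."""
        _, _, truth, d, panel = big_cohort
        design = CohortDesign(
            n_no_tbi=2000, n_mild=1500, n_moderate_severe=1500, n_indeterminate=0,
            severity_interaction_multipliers={"mild": 0.5, "moderate_severe": 1.5},
        )
        ph = simulate_cohort_phenotypes(d, truth, design, seed=77)
        table = assoc.compute_ratio_and_standardize(ph)
        prs_std = true_prs(d, truth).to_numpy()
        res = assoc.severity_ancova(table, prs_std)
        s = res.cell_slopes
        assert s["moderate_severe"] < s["mild"] < s["none"]
        assert res.p < 0.05

    def test_empty_level_error(self):
        rng = np.random.default_rng(13)
        t = _pheno_frame(30, rng, tbi=np.zeros(30, dtype=int))
        t = assoc.compute_ratio_and_standardize(t)
        with pytest.raises(ValueError, match="mild"):
            assoc.severity_ancova(t, rng.normal(size=30))


class TestApoeModels:
    def test_carrier_effect_recovery(self):
        """Planted carrier effect -1.12 recovered within +/-0.1 at n = 4000."""
        d, panel = simulate_genotype_panel(
            4000, 100, maf_range=(0.1, 0.4), dosage_noise_sd=0.02,
            missing_fraction=0.0, seed=41, apoe_fraction=0.1,
        )
        _, truth = simulate_summary_stats(panel, prop_causal=0.2, seed=41)
        # tag deliberately outside the causal set so carrier status is
        # independent of the polygenic score
        non_causal = [s for s in panel["snp_id"] if s not in truth.causal_betas]
        truth.apoe_tag_snp = non_causal[0]
        design = CohortDesign(n_no_tbi=2000, n_mild=2000, n_moderate_severe=0,
                              n_indeterminate=0)
        ph = simulate_cohort_phenotypes(d, truth, design, seed=41)
        table = assoc.compute_ratio_and_standardize(ph)
        fits = assoc.apoe_models(table, true_prs(d, truth).to_numpy())
        b = fits["e4_carrier"].term("carrier")["B"]
        assert b == pytest.approx(truth.effect_apoe_carrier, abs=0.1)

    def test_constant_carrier_errors(self):
        rng = np.random.default_rng(14)
        t = _pheno_frame(30, rng, e4=np.zeros(30, dtype=int))
        t = assoc.compute_ratio_and_standardize(t)
        with pytest.raises(ValueError, match="collinear|aliased"):
            assoc.apoe_models(t, rng.normal(size=30))

    def test_equivalence_when_region_carries_no_weight(self, tmp_path):
        """With no scored SNPs in the APOE region, the region-excluded
        interaction model equals model 3 exactly."""
        from tbiprs import genotype_qc as gqc
        from tbiprs import prs_scoring as prs_mod

        d, panel = simulate_genotype_panel(
            120, 300, seed=55, apoe_fraction=0.0, missing_fraction=0.0
        )
        ss, truth = simulate_summary_stats(panel, seed=55)
        truth.apoe_tag_snp = panel["snp_id"].iloc[5]  # carrier must vary
        design = CohortDesign(n_no_tbi=60, n_mild=30, n_moderate_severe=30,
                              n_indeterminate=0)
        ph = simulate_cohort_phenotypes(d, truth, design, seed=55)
        table = assoc.compute_ratio_and_standardize(ph)
        calls = gqc.hard_call(d)
        aligned, _ = gqc.harmonize_alleles(ss, panel)
        m_full = prs_mod.score_all_thresholds(calls, aligned)
        m_no = prs_mod.score_all_thresholds(calls, aligned, exclude=gqc.APOE_REGION)
        col = prs_mod.threshold_column(0.5, standardized=True)
        fits3 = assoc.fit_hierarchical_models(table, m_full.standardized[col].to_numpy())
        fitsA = assoc.apoe_models(table, m_no.standardized[col].to_numpy())
        np.testing.assert_allclose(
            fitsA["prs_no_apoe"].term("tbi:prs")["B"],
            fits3["model3"].term("tbi:prs")["B"],
            atol=1e-12,
        )


class TestDescriptives:
    def test_counts_and_percentages(self):
        rng = np.random.default_rng(15)
        e4 = np.array([0] * 65 + [1] * 22 + [2] * 1)
        t = assoc.compute_ratio_and_standardize(_pheno_frame(88, rng, e4=e4))
        desc = assoc.descriptives(t)
        row = desc[desc["variable"] == "e4_noncarrier"].iloc[0]
        assert row["total"] == "65 (74%)"
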