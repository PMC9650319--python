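"""Stage two: heterogeneity contrasts, interaction corroboration, sex
contrast and the pooled-sample re-analysis."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apoeqtl import assoc, gqc, hetero
from apoeqtl.containers import EffectPlan
from apoeqtl.syndata import SimConfig, simulate_cohort

finite = st.floats(-5, 5, allow_nan=False)
pos = st.floats(0.01, 3, allow_nan=False)


class TestContrastChisq:
    def test_reference_row_reproduces_printed_statistic(self):
        # dimethylglycine, E2 vs E3: printed 20.013 from unrounded inputs
        chi2 = hetero.contrast_chisq(0.813, 0.196, -0.102, 0.058)
        assert chi2 == pytest.approx(20.013, rel=0.003)

    def test_propionate_row(self):
        chi2 = hetero.contrast_chisq(-0.711, 0.189, -0.012, 0.077)
        assert chi2 == pytest.approx(11.716, rel=0.003)

    def test_equal_effects_give_zero(self):
        assert hetero.contrast_chisq(0.4, 0.1, 0.4, 0.2) == 0.0

    def test_hand_arithmetic(self):
        assert hetero.contrast_chisq(1.0, 0.5, 0.0, 0.5) == pytest.approx(2.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(hetero.HeteroError):
            hetero.contrast_chisq(1.0, 0.0, 0.0, 0.5)

    @settings(max_examples=100, deadline=None)
    @given(finite, pos, finite, pos)
    def test_symmetric_under_group_swap(self, b1, se1, b2, se2):
        assert hetero.contrast_chisq(b1, se1, b2, se2) == pytest.approx(
            hetero.contrast_chisq(b2, se2, b1, se1), rel=1e-12)

    def test_type_one_error_at_nominal_level(self, rng):
        """Null pairs (b1, b2 estimating the same effect): rejection rate of
        the 1-df contrast at 0.05 stays within its binomial band over
        10,000 replicates."""
        n = 10_000
        se1 = rng.uniform(0.05, 0.3, n)
        se2 = rng.uniform(0.05, 0.3, n)
        mu = rng.normal(0, 0.5, n)
        b1 = mu + se1 * rng.standard_normal(n)
        b2 = mu + se2 * rng.standard_normal(n)
        chi2 = (b1 - b2) ** 2 / (se1**2 + se2**2)
        p = np.array([hetero.chisq_pvalue_df1(c) for c in chi2])
        rate = (p < 0.05).mean()
        assert 0.044 <= rate <= 0.056


class TestChisqPvalue:
    @pytest.mark.parametrize("chi2, printed", [
        (9.274, 2.32e-3), (2.778, 9.56e-2), (9.778, 1.77e-3),
        (10.803, 1.01e-3), (8.472, 3.61e-3),
    ])
    def test_reproduces_printed_tail_probabilities(self, chi2, printed):
        assert hetero.chisq_pvalue_df1(chi2) == pytest.approx(printed, rel=5e-3)

    def test_zero_statistic(self):
        assert hetero.chisq_pvalue_df1(0.0) == 1.0

    def test_equals_two_sided_normal_tail(self):
        for x in np.linspace(0, 40, 161):
            expected = 2 * (1 - stats.norm.cdf(np.sqrt(x)))
            assert hetero.chisq_pvalue_df1(x) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(hetero.HeteroError):
            hetero.chisq_pvalue_df1(-0.1)


class TestBonferroni:
    def test_study_family_of_70(self):
        assert hetero.bonferroni_threshold(0.05, 70) == pytest.approx(7.14e-4,
                                                                      rel=1e-3)

    def test_single_test(self):
        assert hetero.bonferroni_threshold(0.05, 1) == 0.05

    def test_hand_arithmetic(self):
        assert hetero.bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)

    def test_zero_family_rejected(self):
        with pytest.raises(hetero.HeteroError):
            hetero.bonferroni_threshold(0.05, 0)


def stage_one_tables(rows):
    """Build (discoveries, results) frames from (stratum, snp, met, beta, se)."""
    results = pd.DataFrame(rows, columns=["stratum", "snp_id", "metabolite_id",
                                          "beta", "se"])
    results["p"] = 2 * stats.norm.sf(np.abs(results.beta / results.se))
    results["q"] = results["p"]
    results["gene_label"] = "G1"
    results["metabolite_class"] = "polar"
    results["n_used"] = 100
    discoveries = results[results["q"] < 0.05].reset_index(drop=True)
    return discoveries, results


class TestFindGroupSpecific:
    def test_reference_inputs_flag_e2_vs_e3_with_opposite_direction(self):
        rows = [("E2", "rs16979759", "dimethylglycine", 0.813, 0.196),
                ("E3", "rs16979759", "dimethylglycine", -0.102, 0.058),
                ("E4", "rs16979759", "dimethylglycine", 0.148, 0.082)]
        disc, res = stage_one_tables(rows)
        out = hetero.find_group_specific(disc, res, m=70)
        row = out[out.pair == "E2_vs_E3"].iloc[0]
        assert row.significant and row.opposite_direction
        assert row.chi2 == pytest.approx(20.013, rel=0.003)
        e2e4 = out[out.pair == "E2_vs_E4"].iloc[0]
        assert e2e4.chi2 == pytest.approx(9.778, rel=0.005)
        assert not e2e4.significant and e2e4.nominal

    def test_identical_results_never_significant(self):
        rows = [(s, "snp1", "m1", 0.5, 0.05) for s in ("E2", "E3", "E4")]
        disc, res = stage_one_tables(rows)
        out = hetero.find_group_specific(disc, res, m=10)
        assert not out["significant"].any()
        assert (out["chi2"] == 0).all()

    def test_duplicated_discoveries_contrasted_once(self):
        rows = [("E2", "snp1", "m1", 0.9, 0.05),
                ("E3", "snp1", "m1", 0.8, 0.05),
                ("E4", "snp1", "m1", 0.7, 0.05)]
        disc, res = stage_one_tables(rows)
        out = hetero.find_group_specific(disc, res, m=3)
        assert len(out) == 3  # three pairs, one (snp, met)

    def test_missing_stratum_marked_untestable(self):
        rows = [("E2", "snp1", "m1", 0.9, 0.05)]
        disc, res = stage_one_tables(rows)
        out = hetero.find_group_specific(disc, res, m=1)
        assert not out["testable"].any()

    def test_empty_discoveries(self):
        disc, res = stage_one_tables([("E2", "snp1", "m1", 0.0, 1.0)])
        out = hetero.find_group_specific(disc.iloc[:0], res)
        assert len(out) == 0


@pytest.fixture(scope="module")
def hetero_cohort():
    """Mid-size cohort with an E2-specific effect for interaction and
    pooled-scan checks: beta_E2 = +0.8, beta_E4 = -0.2, beta_E3 = 0 on
    polar_001; homogeneous beta = 0.25 on polar_002."""
    plan = EffectPlan(pd.DataFrame([
        dict(snp_id="snp001", metabolite_id="polar_001", stratum="E2",
             beta_true=0.8),
        dict(snp_id="snp001", metabolite_id="polar_001", stratum="E4",
             beta_true=-0.2),
        dict(snp_id="snp002", metabolite_id="polar_002", stratum="all",
             beta_true=0.25),
    ]))
    cfg = SimConfig(n_families=452, n_snps=12, n_lipid=1, n_polar=2, seed=314)
    coh = simulate_cohort(cfg, plan)
    aligned, _ = gqc.align_effect_alleles(coh.genotypes, coh.strata)
    K = assoc.pedigree_kinship(coh.pedigree)
    return coh, aligned, K


class TestInteraction:
    def test_heterogeneous_effect_detected(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        res = hetero.interaction_test(aligned, coh.metabolites, coh.covariates,
                                      K, coh.strata, "snp001", "polar_001",
                                      pair=("E2", "E3"))
        assert res["converged"]
        assert abs(res["beta_int"] - 0.8) < 3 * res["se_int"]
        assert res["p_int"] < 7.14e-4

    def test_homogeneous_effect_interaction_null(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        res = hetero.interaction_test(aligned, coh.metabolites, coh.covariates,
                                      K, coh.strata, "snp002", "polar_002",
                                      pair=("E2", "E3"))
        assert abs(res["beta_int"]) < 3 * res["se_int"]

    def test_group_relabel_negates_coefficient(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        a = hetero.interaction_test(aligned, coh.metabolites, coh.covariates,
                                    K, coh.strata, "snp001", "polar_001",
                                    pair=("E2", "E3"))
        b = hetero.interaction_test(aligned, coh.metabolites, coh.covariates,
                                    K, coh.strata, "snp001", "polar_001",
                                    pair=("E3", "E2"))
        assert a["beta_int"] == pytest.approx(-b["beta_int"], abs=1e-6)
        assert a["p_int"] == pytest.approx(b["p_int"], rel=1e-6)

    def test_contrast_and_interaction_p_agree(self, hetero_cohort):
        """The interaction Wald p tracks the two-sample contrast p on the
        same planted-effect data (the corroboration property)."""
        coh, aligned, K = hetero_cohort
        logp = assoc.log_transform(coh.metabolites)
        ps_contrast, ps_inter = [], []
        for snp in ["snp001", "snp002", "snp003"]:
            fits = {}
            for s in ("E2", "E3"):
                subj = coh.strata.subjects_in(s)
                from apoeqtl.lmm import KinshipLMM
                data = coh.covariates.join(logp.values[["polar_001"]])
                data = data.loc[data.index.intersection(subj)].dropna()
                model = KinshipLMM.from_dataframe(
                    data, "polar_001", list(coh.covariates.columns), K)
                fit = model.fit()
                scan = fit.scan(
                    aligned.subset_subjects(model.subjects).dosage_of(snp),
                    snp_ids=[snp])
                fits[s] = scan.iloc[0]
            chi2 = hetero.contrast_chisq(fits["E2"].beta, fits["E2"].se,
                                         fits["E3"].beta, fits["E3"].se)
            ps_contrast.append(hetero.chisq_pvalue_df1(chi2))
            res = hetero.interaction_test(aligned, coh.metabolites,
                                          coh.covariates, K, coh.strata,
                                          snp, "polar_001", pair=("E2", "E3"))
            ps_inter.append(res["p_int"])
        assert stats.spearmanr(ps_contrast, ps_inter).statistic > 0.9


class TestSexContrast:
    def test_sex_homogeneous_effect_not_flagged(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        entries = pd.DataFrame([
            dict(stratum="E3", snp_id="snp002", metabolite_id="polar_002")])
        out = hetero.sex_contrast(aligned, coh.metabolites, coh.covariates, K,
                                  coh.strata, entries)
        assert out.iloc[0]["testable"]
        assert out.iloc[0]["p"] > 0.01

    def test_identical_effects_give_zero_chi2(self):
        assert hetero.contrast_chisq(0.3, 0.1, 0.3, 0.2) == 0.0


class TestPooledScan:
    def test_homogeneous_effect_stronger_pooled(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        disc = pd.DataFrame([dict(stratum="E3", snp_id="snp002",
                                  metabolite_id="polar_002")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled, overlap = hetero.pooled_scan(
                aligned, coh.metabolites, coh.covariates, K, coh.strata, disc,
                metabolites=["polar_001", "polar_002"])
        row = pooled[(pooled.snp_id == "snp002")
                     & (pooled.metabolite_id == "polar_002")].iloc[0]
        assert overlap.iloc[0]["replicates_pooled"]
        # power monotonicity: the pooled sample (larger n) beats the E3
        # stratum alone for a homogeneous effect
        from apoeqtl.lmm import KinshipLMM

        logp = assoc.log_transform(coh.metabolites)
        subj = coh.strata.subjects_in("E3")
        data = coh.covariates.join(logp.values[["polar_002"]])
        data = data.loc[data.index.intersection(subj)].dropna()
        model = KinshipLMM.from_dataframe(data, "polar_002",
                                          list(coh.covariates.columns), K)
        scan = model.fit().scan(
            aligned.subset_subjects(model.subjects).dosage_of("snp002"),
            snp_ids=["snp002"])
        assert row.p < scan.iloc[0]["p"]

    def test_opposite_sign_effects_cancel_in_pool(self, hetero_cohort):
        # +0.8 in E2, -0.2 in E4, null E3: pooled effect attenuates below
        # the E2 stratum effect
        coh, aligned, K = hetero_cohort
        disc = pd.DataFrame([dict(stratum="E2", snp_id="snp001",
                                  metabolite_id="polar_001")])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled, overlap = hetero.pooled_scan(
                aligned, coh.metabolites, coh.covariates, K, coh.strata, disc,
                metabolites=["polar_001"])
        row = pooled[(pooled.snp_id == "snp001")
                     & (pooled.metabolite_id == "polar_001")].iloc[0]
        assert abs(row.beta) < 0.4  # far below the E2-specific 0.8

    def test_empty_discovery_set(self, hetero_cohort):
        coh, aligned, K = hetero_cohort
        disc = pd.DataFrame(columns=["stratum", "snp_id", "metabolite_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, overlap = hetero.pooled_scan(
                aligned, coh.metabolites, coh.covariates, K, coh.strata, disc,
                metabolites=["polar_001"])
        assert len(overlap) == 0
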