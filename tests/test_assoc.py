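"""Stage one: kinship, PCs, the mixed model, BH-FDR and the stratified scan."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apoeqtl import assoc
from apoeqtl.containers import GenotypeMatrix, MetabolitePanel, Pedigree
from apoeqtl.lmm import KinshipLMM, LmmError
from apoeqtl.syndata import SimConfig, simulate_cohort


def make_genotypes(dosage, subjects=None):
    dosage = np.asarray(dosage, dtype=float)
    n, s = dosage.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    snps = pd.DataFrame(
        {"chrom": "19", "pos": 1000 + 10 * np.arange(s),
         "allele_minor": "A", "allele_major": "G", "gene_label": "G1"},
        index=pd.Index([f"snp{j}" for j in range(s)], name="snp_id"),
    )
    return GenotypeMatrix(subjects, snps, dosage)


class TestLogTransform:
    def test_values(self):
        panel = MetabolitePanel(
            pd.DataFrame({"m1": [1.0, np.e**2]}, index=["a", "b"]),
            {"m1": "polar"})
        out = assoc.log_transform(panel)
        assert out.values["m1"].tolist() == pytest.approx([0.0, 2.0])

    def test_nonpositive_raises_naming_culprit(self):
        panel = MetabolitePanel(
            pd.DataFrame({"m1": [1.0, 0.0]}, index=["a", "b"]),
            {"m1": "polar"})
        with pytest.raises(assoc.AssocError, match="m1.*'b'"):
            assoc.log_transform(panel)


class TestPedigreeKinship:
    def test_textbook_relationships(self, toy_pedigree):
        K = assoc.pedigree_kinship(toy_pedigree).to_frame()
        assert K.loc["dad", "gf"] == 0.5        # parent-offspring
        assert K.loc["kid1", "kid2"] == 0.5     # full sibs
        assert K.loc["kid1", "gf"] == 0.25      # grandparent
        assert K.loc["gf", "gm"] == 0.0         # founders unrelated
        assert K.loc["kid1", "kid1"] == 1.0     # non-inbred diagonal

    def test_half_siblings(self):
        ped = Pedigree(pd.DataFrame(
            [("f", "dad", "0", "0", "male"), ("f", "m1", "0", "0", "female"),
             ("f", "m2", "0", "0", "female"), ("f", "h1", "dad", "m1", "male"),
             ("f", "h2", "dad", "m2", "male")],
            columns=["family_id", "individual_id", "father_id", "mother_id",
                     "sex"]))
        K = assoc.pedigree_kinship(ped).to_frame()
        assert K.loc["h1", "h2"] == 0.25

    def test_matches_monte_carlo_gene_dropping(self, toy_pedigree, rng):
        # IBD oracle: drop distinct founder allele labels 1e5 times and
        # count allele sharing; 2*Phi(i,j) = E[# shared alleles by descent]/2...
        # estimated directly as the mean kinship of sampled alleles.
        n_rep = 100_000
        founders = list(toy_pedigree.founder_ids)
        labels = {f: (2 * i, 2 * i + 1) for i, f in enumerate(founders)}
        order = ["gf", "gm", "mom", "dad", "kid1", "kid2"]
        alleles = {f: np.tile(labels[f], (n_rep, 1)) for f in founders}
        for iid in ("dad", "kid1", "kid2"):
            fa, mo = toy_pedigree.parents_of(iid)
            pick_f = rng.integers(2, size=n_rep)
            pick_m = rng.integers(2, size=n_rep)
            alleles[iid] = np.column_stack([
                alleles[fa][np.arange(n_rep), pick_f],
                alleles[mo][np.arange(n_rep), pick_m]])
        K = assoc.pedigree_kinship(toy_pedigree).to_frame()
        for a, b in [("dad", "gf"), ("kid1", "kid2"), ("kid1", "gf"),
                     ("kid1", "mom")]:
            xa, xb = alleles[a], alleles[b]
            share = np.zeros(n_rep)
            for i in range(2):
                for j in range(2):
                    share += (xa[:, i] == xb[:, j])
            phi_hat = share.mean() / 4.0
            assert abs(2 * phi_hat - K.loc[a, b]) < 0.01

    def test_cycle_rejected(self):
        bad = pd.DataFrame(
            [("f", "a", "b", "c", "male"), ("f", "b", "a", "c", "male"),
             ("f", "c", "0", "0", "female")],
            columns=["family_id", "individual_id", "father_id", "mother_id",
                     "sex"])
        with pytest.raises(Exception):
            assoc.pedigree_kinship(Pedigree(bad))


class TestEmpiricalGrm:
    def test_duplicate_individuals(self, rng):
        d = rng.binomial(2, 0.3, size=(1, 50)).astype(float)
        g = make_genotypes(np.vstack([d, d]))
        K = assoc.empirical_grm(g).values
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_unrelated_founders_near_zero(self, rng):
        d = rng.binomial(2, 0.3, size=(30, 500)).astype(float)
        K = assoc.empirical_grm(make_genotypes(d)).values
        off = K[np.triu_indices(30, k=1)]
        assert np.abs(off).max() < 0.25
        assert abs(off.mean()) < 0.05

    def test_monomorphic_skipped_with_warning(self, rng):
        d = rng.binomial(2, 0.3, size=(20, 5)).astype(float)
        d[:, 0] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            assoc.empirical_grm(make_genotypes(d))


class TestGenotypePcs:
    def test_rank_one_pc_tracks_the_snp(self, rng):
        n = 30
        d = np.column_stack([rng.binomial(2, 0.5, n)] * 1).astype(float)
        g = make_genotypes(d)
        ped = Pedigree(pd.DataFrame(
            [(f"f{i}", s, "0", "0", "male") for i, s in enumerate(g.subjects)],
            columns=["family_id", "individual_id", "father_id", "mother_id",
                     "sex"]))
        pcs = assoc.genotype_pcs(g, ped, k=1)
        r = np.corrcoef(pcs["PC1"], d[:, 0])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_founder_scores_orthogonal(self, small_cohort):
        pcs = assoc.genotype_pcs(small_cohort.genotypes, small_cohort.pedigree,
                                 k=3)
        founders = small_cohort.pedigree.founder_ids
        F = pcs.loc[founders].to_numpy()
        gram = F.T @ F
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_two_ancestry_clusters_separated(self, rng):
        n, s = 60, 80
        maf_a = rng.uniform(0.1, 0.3, s)
        maf_b = np.clip(maf_a + 0.4, 0.05, 0.95)
        d = np.vstack([rng.binomial(2, maf_a, size=(n // 2, s)),
                       rng.binomial(2, maf_b, size=(n // 2, s))]).astype(float)
        g = make_genotypes(d)
        ped = Pedigree(pd.DataFrame(
            [(f"f{i}", sbj, "0", "0", "male")
             for i, sbj in enumerate(g.subjects)],
            columns=["family_id", "individual_id", "father_id", "mother_id",
                     "sex"]))
        pcs = assoc.genotype_pcs(g, ped, k=2)
        cluster = np.repeat([0, 1], n // 2)
        r = np.corrcoef(pcs["PC1"], cluster)[0, 1]
        assert abs(r) > 0.9

    def test_k_exceeding_rank_rejected(self, rng):
        d = rng.binomial(2, 0.4, size=(5, 3)).astype(float)
        g = make_genotypes(d)
        ped = Pedigree(pd.DataFrame(
            [(f"f{i}", s, "0", "0", "male") for i, s in enumerate(g.subjects)],
            columns=["family_id", "individual_id", "father_id", "mother_id",
                     "sex"]))
        with pytest.raises(assoc.AssocError):
            assoc.genotype_pcs(g, ped, k=4)


class TestKinshipLmm:
    def olsdata(self, rng, n=120, p=3):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        beta = rng.standard_normal(p)
        y = X @ beta + rng.standard_normal(n)
        return y, X

    def test_identity_kinship_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        y, X = self.olsdata(rng)
        g = rng.binomial(2, 0.3, len(y)).astype(float)
        fit = KinshipLMM(y, X, np.eye(len(y))).fit()
        # total variance equals the OLS residual variance
        ols_null = sm.OLS(y, X).fit()
        assert fit.sigma2 == pytest.approx(ols_null.mse_resid, abs=1e-6)
        scan = fit.scan(g[:, None], snp_ids=["g"])
        ols = sm.OLS(y, np.column_stack([X, g])).fit()
        assert scan.loc["g", "beta"] == pytest.approx(ols.params[-1], abs=1e-8)
        assert scan.loc["g", "se"] == pytest.approx(ols.bse[-1], abs=1e-8)

    def test_allele_flip_equivariance(self, rng):
        y, X = self.olsdata(rng)
        K = np.eye(len(y))
        g = rng.binomial(2, 0.3, len(y)).astype(float)
        fit = KinshipLMM(y, X, K).fit()
        a = fit.scan(g[:, None], snp_ids=["g"]).iloc[0]
        b = fit.scan((2.0 - g)[:, None], snp_ids=["g"]).iloc[0]
        assert a.beta == pytest.approx(-b.beta, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_monomorphic_and_collinear_flagged(self, rng):
        y, X = self.olsdata(rng)
        fit = KinshipLMM(y, X, np.eye(len(y))).fit()
        G = np.column_stack([np.zeros(len(y)), X[:, 1] > np.inf])
        G[:, 1] = 1.0  # constant = collinear with intercept
        scan = fit.scan(G, snp_ids=["mono", "const"])
        assert scan.loc["mono", "reason"] == "monomorphic"
        assert np.isnan(scan.loc["mono", "beta"])

    def test_reml_recovers_heritability_in_sib_design(self):
        # sigma_g2 = sigma_e2 = 0.5 in sib pairs: mean h2 over replicates
        ests = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n_fam = 250
            K = np.kron(np.eye(n_fam), np.array([[1.0, 0.5], [0.5, 1.0]]))
            n = 2 * n_fam
            L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
            y = (np.sqrt(0.5) * (L @ rng.standard_normal(n))
                 + np.sqrt(0.5) * rng.standard_normal(n))
            fit = KinshipLMM(y, np.ones((n, 1)), K).fit()
            ests.append(fit.heritability)
        assert 0.4 <= np.mean(ests) <= 0.6

    def test_degenerate_zero_residual_flagged_or_boundary(self):
        n = 30
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ np.array([1.0, 2.0])  # exact fit, zero residual
        fit = KinshipLMM(y, X, np.eye(n)).fit()
        assert (not fit.converged) or fit.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_rejected(self):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(LmmError):
            KinshipLMM(np.zeros(n), X, np.eye(n))


def bh_definition_oracle(p):
    """Direct step-up definition: q(i) = min_{j: p(j) >= p(i)} p(j)*m/rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cands = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i] - 1e-300]
        q[i] = min(1.0, min(cands))
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        q = assoc.bh_fdr([0.001, 0.01, 0.02, 0.04])
        assert q == pytest.approx([0.004, 0.02, 0.0266667, 0.04], rel=1e-4)

    def test_all_equal_collapse(self):
        assert assoc.bh_fdr([0.05, 0.05, 0.05]) == pytest.approx([0.05] * 3)

    def test_single_test(self):
        assert assoc.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_nan_preserved_and_family_size(self):
        q = assoc.bh_fdr([0.01, np.nan, 0.04], m=10)
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(min(0.01 * 10 / 1, 0.04 * 10 / 2))

    def test_out_of_range_rejected(self):
        with pytest.raises(assoc.AssocError):
            assoc.bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_matches_definition_and_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests

        q = assoc.bh_fdr(p)
        assert np.allclose(q, bh_definition_oracle(p), atol=1e-12)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


class TestNullCalibration:
    def test_wald_type_one_error_with_family_structure(self):
        """Type-I error of the scan at 0.05 under family confounding: the
        kinship term must absorb the polygenic correlation.  10,000 null
        tests (500 null analytes x 20 SNPs) on one simulated cohort."""
        cfg = SimConfig(n_families=100, n_snps=20, n_lipid=250, n_polar=250,
                        seed=77, covariate_effects={})
        coh = simulate_cohort(cfg)
        K = assoc.pedigree_kinship(coh.pedigree)
        logp = assoc.log_transform(coh.metabolites)
        X = np.column_stack([np.ones(coh.pedigree.n_individuals),
                             coh.covariates["sex"].to_numpy()])
        eig = None
        pvals = []
        for met in logp.metabolite_ids:
            y = logp.values[met].to_numpy()
            model = KinshipLMM(y, X, K.values)
            if eig is not None:
                model.set_kinship_eigen(*eig)
            fit = model.fit()
            if eig is None:
                d, U, _, _ = model._eigen()
                eig = (d, U)
            scan = fit.scan(coh.genotypes.subset_snps(
                [f"snp{j + 1:03d}" for j in range(20)]).dosage)
            pvals.extend(scan["p"].tolist())
        pvals = np.asarray(pvals)
        assert len(pvals) == 10_000
        rate = (pvals < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestStratifiedScan:
    def test_planted_effect_discovered_in_e2_not_e3(self, planted_cohort):
        from apoeqtl import gqc

        coh = planted_cohort
        aligned, _ = gqc.align_effect_alleles(coh.genotypes, coh.strata)
        K = assoc.pedigree_kinship(coh.pedigree)
        pcs = assoc.genotype_pcs(aligned, coh.pedigree, k=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res, disc = assoc.run_stratified_scan(
                aligned, coh.metabolites, coh.covariates, K, coh.strata,
                pcs=pcs)
        e2_hits = disc[(disc.stratum == "E2") & (disc.snp_id == "snp001")
                       & (disc.metabolite_id == "polar_001")]
        assert len(e2_hits) == 1
        beta, se = e2_hits.iloc[0][["beta", "se"]]
        assert abs(beta - 0.8) < 3 * se
        e3_hits = disc[(disc.stratum == "E3") & (disc.snp_id == "snp001")
                       & (disc.metabolite_id == "polar_001")]
        assert len(e3_hits) == 0
        # q is BH within stratum and never smaller than p (tested rows)
        ok = res["p"].notna()
        assert (res.loc[ok, "q"] >= res.loc[ok, "p"] - 1e-12).all()

    def test_determinism(self, small_cohort):
        coh = small_cohort
        K = assoc.pedigree_kinship(coh.pedigree)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1, _ = assoc.run_stratified_scan(coh.genotypes, coh.metabolites,
                                              coh.covariates, K, coh.strata)
            r2, _ = assoc.run_stratified_scan(coh.genotypes, coh.metabolites,
                                              coh.covariates, K, coh.strata)
        pd.testing.assert_frame_equal(r1, r2)
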