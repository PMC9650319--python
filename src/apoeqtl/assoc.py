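"""Stage one: per-stratum additive SNP-metabolite association scans.

For every APOE stratum and every metabolite, a kinship linear mixed model
is fitted under the null (log concentration ~ covariates + top genetic
principal components + family random effect), variance components are
estimated once by REML, and every SNP is then tested by generalized least
squares with the heritability ratio held fixed.  Discoveries are declared
at Benjamini-Hochberg FDR < 0.05, with the multiplicity family being all
tests within one stratum by default (per-metabolite families optional).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    GenotypeMatrix,
    KinshipMatrix,
    MetabolitePanel,
    Pedigree,
    StratumAssignment,
    STRATA,
)
from .lmm import KinshipLMM, KinshipLMMResults

__all__ = [
    "log_transform",
    "pedigree_kinship",
    "empirical_grm",
    "genotype_pcs",
    "fit_null_reml",
    "snp_scan",
    "bh_fdr",
    "run_stratified_scan",
]


class AssocError(ValueError):
    pass


def log_transform(panel: MetabolitePanel) -> MetabolitePanel:
    """Natural log of every concentration; missing values preserved.

    Raises on any non-positive value (naming analyte and subject) rather
    than silently adding a pseudocount: the concentrations are defined as
    strictly positive and a zero signals an upstream data problem.
    """
    vals = panel.values
    bad = (vals <= 0).any()
    if bad.any():
        analyte = bad.index[bad.argmax()]
        col = vals[analyte]
        subject = col.index[(col <= 0).argmax()]
        raise AssocError(
            f"non-positive concentration for analyte {analyte!r}, "
            f"subject {subject!r}; log transform requires positive values"
        )
    return MetabolitePanel(np.log(vals), panel.classes)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def pedigree_kinship(ped: Pedigree) -> KinshipMatrix:
    """Expected relationship matrix 2*Phi from the pedigree.

    Recursive kinship: founders are unrelated and non-inbred,
    Phi(i,i) = (1 + Phi(father_i, mother_i)) / 2 and, for i not an ancestor
    of j, Phi(i,j) = (Phi(father_i, j) + Phi(mother_i, j)) / 2.  Computed
    family by family (across-family entries are zero), so the result is
    block diagonal in pedigree order.
    """
    ids = list(ped.individual_ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for _, fam in ped.families():
        members = list(fam["individual_id"])
        order: list[str] = []
        placed: set[str] = set()
        pending = list(members)
        while pending:
            progressed = False
            rest = []
            for iid in pending:
                parents = ped.parents_of(iid)
                if all(p in placed or p not in set(members) for p in parents):
                    order.append(iid)
                    placed.add(iid)
                    progressed = True
                else:
                    rest.append(iid)
            if not progressed:
                raise AssocError(f"cannot topologically order family {fam.name!r}")
            pending = rest
        phi: dict[tuple[str, str], float] = {}

        def get(a: str, b: str) -> float:
            return phi.get((a, b), phi.get((b, a), 0.0))

        for idx_i, i in enumerate(order):
            parents = ped.parents_of(i)
            if len(parents) == 2:
                phi[(i, i)] = 0.5 * (1.0 + get(parents[0], parents[1]))
            else:
                phi[(i, i)] = 0.5
            for j in order[:idx_i]:
                if len(parents) == 2:
                    phi[(i, j)] = 0.5 * (get(parents[0], j) + get(parents[1], j))
                else:
                    phi[(i, j)] = 0.0
        for (a, b), v in phi.items():
            A[pos[a], pos[b]] = 2.0 * v
            A[pos[b], pos[a]] = 2.0 * v
    return KinshipMatrix(ids, A)


def empirical_grm(g: GenotypeMatrix) -> KinshipMatrix:
    """GCTA-style genomic relationship matrix from standardized dosages.

    Entry (i, j) is the mean over polymorphic SNPs of
    (d_i - 2f)(d_j - 2f) / (2 f (1 - f)); missing calls are mean-imputed
    and monomorphic SNPs skipped with a warning.
    """
    D = g.dosage.copy()
    means = np.nanmean(D, axis=0)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(means, inds[1])
    f = means / 2.0
    poly = (f > 0) & (f < 1)
    if poly.sum() < 2:
        raise AssocError("need at least 2 polymorphic SNPs for a GRM")
    if (~poly).any():
        warnings.warn(f"skipping {int((~poly).sum())} monomorphic SNPs in GRM")
    Z = (D[:, poly] - 2 * f[poly]) / np.sqrt(2 * f[poly] * (1 - f[poly]))
    A = Z @ Z.T / poly.sum()
    return KinshipMatrix(list(g.subjects), A)


# ---------------------------------------------------------------------------
# genetic principal components
# ---------------------------------------------------------------------------

def genotype_pcs(g: GenotypeMatrix, ped: Pedigree, k: int = 5) -> pd.DataFrame:
    """Top-k PCs of the standardized dosage matrix.

    Loadings are computed on founders only (family structure inflates PCs)
    and all subjects, founders and offspring alike, are projected onto
    them.  Deterministic up to sign; the sign is fixed by making each
    loading vector's largest-magnitude entry positive.
    """
    if k < 1:
        raise AssocError("k must be >= 1")
    founders = set(ped.founder_ids)
    fmask = np.array([s in founders for s in g.subjects])
    if fmask.sum() < 2:
        raise AssocError("need at least 2 founders for PC estimation")
    D = g.dosage.copy()
    col_mean = np.nanmean(D[fmask], axis=0)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(col_mean, inds[1])
    sd = D[fmask].std(axis=0, ddof=0)
    keep = sd > 0
    Z = (D[:, keep] - col_mean[keep]) / sd[keep]
    Zf = Z[fmask]
    rank = np.linalg.matrix_rank(Zf - Zf.mean(axis=0))
    if k > rank:
        raise AssocError(f"k={k} exceeds founder genotype rank {rank}")
    _, _, Vt = np.linalg.svd(Zf - Zf.mean(axis=0), full_matrices=False)
    V = Vt[:k].T
    for j in range(k):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    scores = (Z - Zf.mean(axis=0)) @ V
    return pd.DataFrame(scores, index=g.subjects,
                        columns=[f"PC{i + 1}" for i in range(k)])


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_null_reml(y, X, K, **kwargs) -> KinshipLMMResults:
    """REML fit of the null (no-SNP) model; thin functional wrapper around
    :class:`~apoeqtl.lmm.KinshipLMM`."""
    return KinshipLMM(y, X, K, **kwargs).fit()


def snp_scan(fit: KinshipLMMResults, g: GenotypeMatrix,
             subjects=None) -> pd.DataFrame:
    """Test every SNP against the fitted null model (see
    :meth:`KinshipLMMResults.scan`); ``subjects`` selects/aligns the dosage
    rows with the model observations."""
    sub = g if subjects is None else g.subset_subjects(subjects)
    return fit.scan(sub.dosage, snp_ids=sub.snp_ids)


def bh_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    q(i) = min over j with p(j) >= p(i) of p(j) * m / rank(j), capped at 1;
    ``m`` defaults to the number of (non-missing) p-values but may be set
    larger to count untested hypotheses in the family.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise AssocError("p-values must lie in [0, 1]")
    k = pv.size
    if k == 0:
        return out
    m_eff = k if m is None else int(m)
    if m_eff < k:
        raise AssocError("family size m cannot be smaller than the number of tests")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m_eff / np.arange(1, k + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(k)
    adj[order] = q
    out[mask] = adj
    return out


# ---------------------------------------------------------------------------
# stratified scan
# ---------------------------------------------------------------------------

def _covariate_design(covariates: pd.DataFrame, pcs: pd.DataFrame | None) -> pd.DataFrame:
    X = covariates.copy()
    if pcs is not None:
        X = X.join(pcs, how="inner")
    return X


def run_stratified_scan(
    genotypes: GenotypeMatrix,
    panel: MetabolitePanel,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    strata: StratumAssignment,
    pcs: pd.DataFrame | None = None,
    fdr: float = 0.05,
    fdr_family: str = "stratum",
    min_stratum_size: int = 50,
    strata_list=STRATA,
    log: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full stage-one analysis in each APOE stratum.

    Returns ``(results, discoveries)``: one row per (stratum, SNP,
    metabolite) test with beta/se/p/q, and the q < ``fdr`` subset sorted by
    stratum then q.  ``fdr_family`` is ``"stratum"`` (BH over all tests in
    a stratum, the default) or ``"metabolite"`` (BH within each
    (stratum, metabolite) family).
    """
    if fdr_family not in ("stratum", "metabolite"):
        raise AssocError("fdr_family must be 'stratum' or 'metabolite'")
    logp = log_transform(panel) if log else panel
    design = _covariate_design(covariates, pcs)
    covnames = list(design.columns)
    rows = []
    eig_cache: dict[tuple, tuple] = {}
    for stratum in strata_list:
        subjects = strata.subjects_in(stratum)
        subjects = subjects.intersection(genotypes.subjects)
        if len(subjects) < min_stratum_size:
            warnings.warn(
                f"stratum {stratum} has only {len(subjects)} subjects "
                f"(minimum {min_stratum_size}); running anyway"
            )
        if len(subjects) == 0:
            continue
        for met in logp.metabolite_ids:
            data = design.join(logp.values[[met]], how="inner")
            data = data.loc[data.index.intersection(subjects)]
            data = data.dropna()
            if len(data) < len(covnames) + 3:
                continue
            model = KinshipLMM.from_dataframe(data, met, covnames, kinship)
            key = (stratum, tuple(model.subjects))
            if key in eig_cache:
                model.set_kinship_eigen(*eig_cache[key])
            fit = model.fit()
            if key not in eig_cache:
                d, U, _, _ = model._eigen()
                eig_cache[key] = (d, U)
            if not fit.converged:
                for snp in genotypes.snp_ids:
                    rows.append((stratum, snp, met, np.nan, np.nan, np.nan,
                                 len(data), "null_fit_failed"))
                continue
            scan = snp_scan(fit, genotypes, subjects=model.subjects)
            for snp, r in scan.iterrows():
                rows.append((stratum, snp, met, r.beta, r.se, r.p,
                             int(r.n_used), r.reason))
    results = pd.DataFrame(
        rows, columns=["stratum", "snp_id", "metabolite_id", "beta", "se", "p",
                       "n_used", "reason"],
    )
    results["gene_label"] = results["snp_id"].map(genotypes.snps["gene_label"])
    results["effect_allele"] = results["snp_id"].map(genotypes.snps["allele_minor"])
    results["metabolite_class"] = results["metabolite_id"].map(panel.classes)

    results["q"] = np.nan
    if fdr_family == "stratum":
        groups = results.groupby("stratum").groups
    else:
        groups = results.groupby(["stratum", "metabolite_id"]).groups
    for _, idx in groups.items():
        results.loc[idx, "q"] = bh_fdr(results.loc[idx, "p"].to_numpy())

    cols = ["stratum", "snp_id", "gene_label", "metabolite_id", "metabolite_class",
            "effect_allele", "beta", "se", "p", "q", "n_used", "reason"]
    results = results[cols]
    discoveries = (
        results[results["q"] < fdr]
        .sort_values(["stratum", "q", "p"])
        .reset_index(drop=True)
    )
    return results, discoveries
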