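"""Supporting diagnostics: LD matrices, multicollinearity, distribution
summaries and gene-by-stratum clustering tabulations.

LD (r-squared and D-prime) is computed on founders only, from true phase
when haplotypes are available and otherwise by two-locus EM estimation of
haplotype frequencies from unphased genotypes.  The multicollinearity
check regresses each SNP's dosage on the full stage-one covariate set and
reports the squared multiple correlation and variance inflation factor
VIF = 1 / (1 - R^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MetabolitePanel, Pedigree, StratumAssignment

__all__ = [
    "ld_from_haplotype_freqs",
    "em_haplotype_freqs",
    "ld_matrix",
    "vif",
    "metabolite_summaries",
    "gene_group_clustering",
]


class DiagnosticsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_from_haplotype_freqs(p_ab: float, p_a: float, p_b: float
                            ) -> tuple[float, float]:
    """(r2, d_prime) from the AB-haplotype frequency and allele frequencies."""
    if not (0 < p_a < 1 and 0 < p_b < 1):
        return np.nan, np.nan
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else (0.0 if d == 0 else np.nan)
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(r2), float(min(d_prime, 1.0))


def em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray, max_iter: int = 50,
                       tol: float = 1e-10) -> tuple[float, float, float]:
    """Two-locus EM estimate of (p_AB, p_A, p_B) from unphased dosages.

    Only the double heterozygote is phase-ambiguous; EM iterates the
    expected split of those subjects between AB/ab and Ab/aB phase.
    """
    ok = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        return np.nan, np.nan, np.nan
    p_a = g1.mean() / 2.0
    p_b = g2.mean() / 2.0
    n_dh = int(((g1 == 1) & (g2 == 1)).sum())
    # unambiguous AB haplotype counts
    n_ab_known = float(
        2 * ((g1 == 2) & (g2 == 2)).sum()
        + ((g1 == 2) & (g2 == 1)).sum()
        + ((g1 == 1) & (g2 == 2)).sum()
    )
    p = {"AB": p_a * p_b, "Ab": p_a * (1 - p_b),
         "aB": (1 - p_a) * p_b, "ab": (1 - p_a) * (1 - p_b)}
    p_ab = p["AB"]
    for _ in range(max_iter):
        denom = p["AB"] * p["ab"] + p["Ab"] * p["aB"]
        frac = (p["AB"] * p["ab"] / denom) if denom > 0 else 0.5
        n_AB = n_ab_known + n_dh * frac
        new_p_ab = n_AB / (2.0 * n)
        new = {
            "AB": new_p_ab,
            "Ab": p_a - new_p_ab,
            "aB": p_b - new_p_ab,
            "ab": 1 - p_a - p_b + new_p_ab,
        }
        new = {k: max(v, 0.0) for k, v in new.items()}
        if abs(new_p_ab - p_ab) < tol:
            p_ab = new_p_ab
            break
        p, p_ab = new, new_p_ab
    return float(p_ab), float(p_a), float(p_b)


def ld_matrix(g: GenotypeMatrix, ped: Pedigree | None = None,
              use_phase: bool = True) -> pd.DataFrame:
    """Square LD matrix: r2 in the lower-left triangle, D' in the
    upper-right, 1.0 on the diagonal.

    Computed on founders when a pedigree is given (relatedness inflates
    LD).  With phased haplotypes present and ``use_phase``, haplotype
    frequencies are counted directly; otherwise they are estimated by EM
    from unphased genotypes.  Pairs with a monomorphic SNP are NaN.
    """
    if g.n_snps < 2:
        raise DiagnosticsError("need at least 2 SNPs for an LD matrix")
    sub = g
    if ped is not None:
        keep = [s for s in g.subjects if s in set(ped.founder_ids)]
        if keep:
            sub = g.subset_subjects(keep)
    S = sub.n_snps
    out = np.full((S, S), np.nan)
    np.fill_diagonal(out, 1.0)
    phased = use_phase and sub.haplotypes is not None
    if phased:
        H = sub.haplotypes.reshape(-1, S).astype(float)  # (2n, S)
    for i in range(S):
        for j in range(i + 1, S):
            if phased:
                hi, hj = H[:, i], H[:, j]
                ok = (hi >= 0) & (hj >= 0)
                if ok.sum() == 0:
                    continue
                p_a, p_b = hi[ok].mean(), hj[ok].mean()
                p_ab = (hi[ok] * hj[ok]).mean()
            else:
                p_ab, p_a, p_b = em_haplotype_freqs(sub.dosage[:, i],
                                                    sub.dosage[:, j])
            r2, d_prime = ld_from_haplotype_freqs(p_ab, p_a, p_b)
            out[j, i] = r2       # lower-left
            out[i, j] = d_prime  # upper-right
    return pd.DataFrame(out, index=sub.snp_ids, columns=sub.snp_ids)


# ---------------------------------------------------------------------------
# multicollinearity
# ---------------------------------------------------------------------------

def vif(g: GenotypeMatrix, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP squared multiple correlation of dosage on the covariate set
    and the corresponding variance inflation factor 1 / (1 - R^2)."""
    cov = covariates.loc[covariates.index.intersection(g.subjects)]
    cov = cov.loc[:, cov.nunique() > 1].dropna()
    sub = g.subset_subjects(cov.index)
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DiagnosticsError("covariate design is rank deficient")
    rows = []
    for j, snp in enumerate(sub.snp_ids):
        d = sub.dosage[:, j]
        ok = ~np.isnan(d)
        dv, Xv = d[ok], X[ok]
        if len(dv) == 0 or dv.std() == 0:
            rows.append((snp, np.nan, np.nan, "constant"))
            continue
        beta, _, _, _ = np.linalg.lstsq(Xv, dv, rcond=None)
        resid = dv - Xv @ beta
        tss = float(((dv - dv.mean()) ** 2).sum())
        r2 = max(0.0, 1.0 - float((resid**2).sum()) / tss)
        r2 = min(r2, 1.0 - 1e-12)
        rows.append((snp, r2, 1.0 / (1.0 - r2), ""))
    out = pd.DataFrame(rows, columns=["snp_id", "r2_covariates", "vif", "reason"])
    out.attrs["r2_range"] = (float(out["r2_covariates"].min()),
                             float(out["r2_covariates"].max()))
    out.attrs["vif_range"] = (float(out["vif"].min()), float(out["vif"].max()))
    return out


# ---------------------------------------------------------------------------
# metabolite distribution summaries
# ---------------------------------------------------------------------------

def metabolite_summaries(panel: MetabolitePanel, strata: StratumAssignment,
                         strata_list=("E2", "E3", "E4")
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(analyte, stratum) mean with normal-approximation 95% CI and a
    mean-different-from-zero test; plus pairwise CI-overlap flags.

    Returns ``(summaries, overlaps)``; strata with fewer than two
    observations get undefined CIs and are flagged untestable.
    """
    rows = []
    for met in panel.metabolite_ids:
        for s in strata_list:
            subj = strata.subjects_in(s).intersection(panel.subjects)
            vals = panel.values.loc[subj, met].dropna().to_numpy(float)
            n = len(vals)
            if n < 2:
                rows.append((met, s, n, np.nan, np.nan, np.nan, np.nan, False))
                continue
            mean = vals.mean()
            sem = vals.std(ddof=1) / np.sqrt(n)
            t_p = stats.ttest_1samp(vals, 0.0).pvalue if sem > 0 else 0.0
            rows.append((met, s, n, mean, mean - 1.96 * sem, mean + 1.96 * sem,
                         float(t_p), True))
    summaries = pd.DataFrame(rows, columns=[
        "metabolite_id", "stratum", "n", "mean", "ci_lo", "ci_hi",
        "p_mean_zero", "testable",
    ])
    keyed = summaries.set_index(["metabolite_id", "stratum"])
    orows = []
    for met in panel.metabolite_ids:
        for i, a in enumerate(strata_list):
            for b in strata_list[i + 1:]:
                ra, rb = keyed.loc[(met, a)], keyed.loc[(met, b)]
                if not (ra["testable"] and rb["testable"]):
                    orows.append((met, a, b, None))
                    continue
                overlap = (ra["ci_lo"] <= rb["ci_hi"]) and (rb["ci_lo"] <= ra["ci_hi"])
                orows.append((met, a, b, bool(overlap)))
    overlaps = pd.DataFrame(orows, columns=["metabolite_id", "stratum_a",
                                            "stratum_b", "ci_overlap"])
    return summaries, overlaps


# ---------------------------------------------------------------------------
# gene-by-stratum clustering
# ---------------------------------------------------------------------------

def gene_group_clustering(discoveries: pd.DataFrame,
                          strata_list=("E2", "E3", "E4")) -> dict[str, pd.DataFrame]:
    """Gene x stratum incidence tables of the discoveries.

    Returns three boolean tables keyed ``"all"``, ``"lipid"`` and
    ``"polar"`` (genes with at least one discovery in a stratum), each with
    per-stratum unique-gene counts in ``.attrs["unique_counts"]``.
    Discoveries without a gene label count under ``"unassigned"``.
    """
    disc = discoveries.copy()
    if "gene_label" not in disc.columns:
        disc["gene_label"] = "unassigned"
    disc["gene_label"] = disc["gene_label"].fillna("unassigned")
    out = {}
    for key in ("all", "lipid", "polar"):
        sub = disc if key == "all" else disc[disc["metabolite_class"] == key]
        genes = sorted(set(sub["gene_label"]))
        table = pd.DataFrame(False, index=pd.Index(genes, name="gene"),
                             columns=list(strata_list))
        for _, r in sub.iterrows():
            if r.stratum in table.columns:
                table.loc[r.gene_label, r.stratum] = True
        unique = {}
        for s in strata_list:
            others = [c for c in strata_list if c != s]
            mask = table[s] & ~table[others].any(axis=1)
            unique[s] = int(mask.sum())
        table.attrs["gene_counts"] = {s: int(table[s].sum()) for s in strata_list}
        table.attrs["unique_counts"] = unique
        out[key] = table
    return out
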