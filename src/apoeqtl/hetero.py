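"""Stage two: cross-stratum effect-heterogeneity analysis.

For every stage-one discovery, the SNP's effect is contrasted between
pairs of APOE strata with the 1-df chi-square statistic

    chi2 = (b1 - b2)^2 / (SE1^2 + SE2^2)

judged at a Bonferroni threshold whose denominator is, by default, the
total number of stage-one discoveries across strata.  Group-specific
associations are corroborated by SNP x group interaction models on the
pooled pair of strata, checked for sex heterogeneity, and compared with a
re-analysis in the pooled (E2 u E3 u E4) sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix, MetabolitePanel, StratumAssignment
from .lmm import KinshipLMM
from .assoc import bh_fdr, log_transform, run_stratified_scan

__all__ = [
    "contrast_chisq",
    "chisq_pvalue_df1",
    "bonferroni_threshold",
    "find_group_specific",
    "interaction_test",
    "sex_contrast",
    "pooled_scan",
]

CONTRAST_PAIRS = (("E2", "E3"), ("E4", "E3"), ("E2", "E4"))


class HeteroError(ValueError):
    pass


def contrast_chisq(b1: float, se1: float, b2: float, se2: float) -> float:
    """Effect-heterogeneity statistic (b1 - b2)^2 / (se1^2 + se2^2).

    Symmetric in the two groups; 1 df under the null of equal effects.
    """
    if se1 <= 0 or se2 <= 0:
        raise HeteroError("standard errors must be positive")
    return (b1 - b2) ** 2 / (se1**2 + se2**2)


def chisq_pvalue_df1(chi2: float) -> float:
    """Upper-tail probability of chi-square with 1 df (= 2*(1 - Phi(sqrt(x))))."""
    if chi2 < 0:
        raise HeteroError("chi-square statistic must be non-negative")
    return float(stats.chi2.sf(chi2, df=1))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if not (0 < alpha < 1):
        raise HeteroError("alpha must be in (0, 1)")
    if m < 1:
        raise HeteroError("m must be >= 1")
    return alpha / m


def find_group_specific(discoveries: pd.DataFrame, results: pd.DataFrame,
                        alpha: float = 0.05, m: int | None = None) -> pd.DataFrame:
    """Contrast every discovery's effect between all three stratum pairs.

    ``discoveries``/``results`` are stage-one tables (see
    :func:`apoeqtl.assoc.run_stratified_scan`).  (snp, metabolite) pairs
    discovered in more than one stratum are contrasted once.  The
    Bonferroni denominator ``m`` defaults to the total discovery count
    across strata.  Returns one row per (snp, metabolite, pair) with the
    stage-one estimates, chi2, p, a ``significant`` flag at alpha/m, a
    ``nominal`` flag at alpha, and ``opposite_direction``.
    """
    m_eff = len(discoveries) if m is None else int(m)
    if m_eff < 1:
        return pd.DataFrame(columns=[
            "snp_id", "metabolite_id", "pair", "group_a", "group_b",
            "b1", "se1", "b2", "se2", "chi2", "p",
            "significant", "nominal", "opposite_direction", "testable",
        ])
    threshold = bonferroni_threshold(alpha, m_eff)
    keyed = results.set_index(["stratum", "snp_id", "metabolite_id"])
    rows = []
    seen = set()
    for _, d in discoveries.iterrows():
        key = (d.snp_id, d.metabolite_id)
        if key in seen:
            continue
        seen.add(key)
        for ga, gb in CONTRAST_PAIRS:
            try:
                ra = keyed.loc[(ga,) + key]
                rb = keyed.loc[(gb,) + key]
            except KeyError:
                rows.append(key + (f"{ga}_vs_{gb}", ga, gb) + (np.nan,) * 6
                            + (False, False, False, False))
                continue
            b1, se1 = float(ra["beta"]), float(ra["se"])
            b2, se2 = float(rb["beta"]), float(rb["se"])
            if not (np.isfinite(se1) and np.isfinite(se2) and se1 > 0 and se2 > 0):
                rows.append(key + (f"{ga}_vs_{gb}", ga, gb, b1, se1, b2, se2,
                                   np.nan, np.nan, False, False, False, False))
                continue
            chi2 = contrast_chisq(b1, se1, b2, se2)
            p = chisq_pvalue_df1(chi2)
            rows.append(key + (f"{ga}_vs_{gb}", ga, gb, b1, se1, b2, se2,
                               chi2, p, p < threshold, p < alpha,
                               bool(np.sign(b1) != np.sign(b2)), True))
    out = pd.DataFrame(rows, columns=[
        "snp_id", "metabolite_id", "pair", "group_a", "group_b",
        "b1", "se1", "b2", "se2", "chi2", "p",
        "significant", "nominal", "opposite_direction", "testable",
    ])
    out.attrs["bonferroni_m"] = m_eff
    out.attrs["bonferroni_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# interaction corroboration
# ---------------------------------------------------------------------------

def interaction_test(genotypes: GenotypeMatrix, panel: MetabolitePanel,
                     covariates: pd.DataFrame, kinship: KinshipMatrix,
                     strata: StratumAssignment, snp_id: str, metabolite_id: str,
                     pair: tuple[str, str] = ("E2", "E3"),
                     pcs: pd.DataFrame | None = None,
                     log: bool = True) -> pd.Series:
    """SNP x group interaction LMM on the pooled pair of strata.

    Fixed effects: stage-one covariates (+ PCs), a binary group indicator
    (1 for ``pair[0]``), the SNP dosage, and dosage x group; the family
    random effect uses the kinship of the pooled subset.  Returns a Series
    with beta_int, se_int, p_int and bookkeeping fields.
    """
    ga, gb = pair
    subjects = strata.subjects_in(ga).union(strata.subjects_in(gb))
    subjects = subjects.intersection(genotypes.subjects)
    logp = log_transform(panel) if log else panel
    data = covariates.copy()
    if pcs is not None:
        data = data.join(pcs, how="inner")
    covnames = list(data.columns)
    data = data.join(logp.values[[metabolite_id]], how="inner")
    data["group"] = strata.labels.reindex(data.index).map({ga: 1.0, gb: 0.0})
    dos = pd.Series(genotypes.dosage_of(snp_id), index=genotypes.subjects)
    data["dosage"] = dos.reindex(data.index)
    data = data.loc[data.index.intersection(subjects)].dropna()
    data["snp_x_group"] = data["dosage"] * data["group"]
    if data["group"].nunique() < 2:
        raise HeteroError("both strata must be represented in the pooled pair")
    model = KinshipLMM.from_dataframe(
        data, metabolite_id, covnames + ["group", "dosage", "snp_x_group"], kinship
    )
    fit = model.fit()
    if not fit.converged or "snp_x_group" not in fit.params.index:
        return pd.Series({"snp_id": snp_id, "metabolite_id": metabolite_id,
                          "pair": f"{ga}_vs_{gb}", "beta_int": np.nan,
                          "se_int": np.nan, "p_int": np.nan,
                          "n_used": len(data), "converged": False})
    return pd.Series({
        "snp_id": snp_id, "metabolite_id": metabolite_id, "pair": f"{ga}_vs_{gb}",
        "beta_int": float(fit.params["snp_x_group"]),
        "se_int": float(fit.bse["snp_x_group"]),
        "p_int": float(fit.pvalues["snp_x_group"]),
        "n_used": fit.n_used, "converged": True,
    })


# ---------------------------------------------------------------------------
# sex heterogeneity
# ---------------------------------------------------------------------------

def sex_contrast(genotypes: GenotypeMatrix, panel: MetabolitePanel,
                 covariates: pd.DataFrame, kinship: KinshipMatrix,
                 strata: StratumAssignment, entries: pd.DataFrame,
                 pcs: pd.DataFrame | None = None, alpha: float = 0.05,
                 min_subgroup: int = 20) -> pd.DataFrame:
    """Male-vs-female effect contrast for selected (stratum, snp, metabolite)
    entries: the stage-one scan is refitted within each sex of the relevant
    stratum (dropping ``sex`` from the design) and the effects contrasted
    at nominal ``alpha``."""
    if "sex" not in covariates.columns:
        raise HeteroError("covariates must include a 'sex' column (1 = female)")
    logp = log_transform(panel)
    rows = []
    for _, e in entries.iterrows():
        sub = strata.subjects_in(e.stratum).intersection(genotypes.subjects)
        fits = {}
        for label, is_female in (("male", 0.0), ("female", 1.0)):
            subj = [s for s in sub if covariates.loc[s, "sex"] == is_female]
            if len(subj) < min_subgroup:
                fits[label] = None
                continue
            design = covariates.drop(columns="sex")
            if pcs is not None:
                design = design.join(pcs, how="inner")
            covnames = list(design.columns)
            data = design.join(logp.values[[e.metabolite_id]], how="inner")
            data = data.loc[data.index.intersection(pd.Index(subj))].dropna()
            model = KinshipLMM.from_dataframe(data, e.metabolite_id, covnames,
                                              kinship)
            fit = model.fit()
            if not fit.converged:
                fits[label] = None
                continue
            scan = fit.scan(
                genotypes.subset_subjects(model.subjects).dosage_of(e.snp_id),
                snp_ids=[e.snp_id],
            )
            fits[label] = scan.iloc[0]
        fm, ff = fits["male"], fits["female"]
        ok = (fm is not None and ff is not None
              and np.isfinite(fm.se) and np.isfinite(ff.se)
              and fm.se > 0 and ff.se > 0)
        if ok:
            chi2 = contrast_chisq(fm.beta, fm.se, ff.beta, ff.se)
            p = chisq_pvalue_df1(chi2)
            rows.append((e.snp_id, e.metabolite_id, e.stratum, fm.beta, fm.se,
                         ff.beta, ff.se, chi2, p, p < alpha, True))
        else:
            rows.append((e.snp_id, e.metabolite_id, e.stratum) + (np.nan,) * 6
                        + (False, False))
    return pd.DataFrame(rows, columns=[
        "snp_id", "metabolite_id", "stratum", "b_male", "se_male",
        "b_female", "se_female", "chi2", "p", "significant", "testable",
    ])


# ---------------------------------------------------------------------------
# pooled-sample re-analysis
# ---------------------------------------------------------------------------

def pooled_scan(genotypes: GenotypeMatrix, panel: MetabolitePanel,
                covariates: pd.DataFrame, kinship: KinshipMatrix,
                strata: StratumAssignment, discoveries: pd.DataFrame,
                pcs: pd.DataFrame | None = None, fdr: float = 0.05,
                group_specific: pd.DataFrame | None = None,
                metabolites: list[str] | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-one re-analysis in the pooled E2 u E3 u E4 sample.

    The pooled sample excludes e2e4 carriers by construction of the
    strata.  BH is applied over the pooled family; the overlap report says
    for each per-stratum discovery whether it replicates (pooled q < fdr)
    and whether it was flagged group-specific.  ``metabolites`` optionally
    restricts the scan (the BH family is then the restricted scan).
    """
    if metabolites is not None:
        panel = MetabolitePanel(panel.values[metabolites],
                                panel.classes[metabolites])
    results, pooled_disc = run_stratified_scan(
        genotypes, panel, covariates, kinship, strata, pcs=pcs, fdr=fdr,
        strata_list=("pooled",),
    )
    keyed = results.set_index(["snp_id", "metabolite_id"])
    gs_keys = set()
    if group_specific is not None and len(group_specific):
        sig = group_specific[group_specific["significant"].fillna(False)]
        gs_keys = set(zip(sig["snp_id"], sig["metabolite_id"]))
    rows = []
    for _, d in discoveries.iterrows():
        key = (d.snp_id, d.metabolite_id)
        try:
            r = keyed.loc[key]
            pooled_q = float(r["q"]) if np.isfinite(r["q"]) else np.nan
            pooled_p = float(r["p"]) if np.isfinite(r["p"]) else np.nan
        except KeyError:
            pooled_q = pooled_p = np.nan
        rows.append((d.stratum, d.snp_id, d.metabolite_id, pooled_p, pooled_q,
                     bool(pooled_q < fdr) if np.isfinite(pooled_q) else False,
                     key in gs_keys))
    overlap = pd.DataFrame(rows, columns=[
        "stratum", "snp_id", "metabolite_id", "pooled_p", "pooled_q",
        "replicates_pooled", "group_specific",
    ])
    return results, overlap
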