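"""Genotype quality control and APOE-group assignment.

QC filters (with the study's default thresholds): minor allele frequency
>= 1%, Hardy-Weinberg exact-test p >= 1e-6, per-SNP and per-subject
missingness <= 5%, and Mendel error rates <= 2% for SNPs, subjects and
families.  Filters are applied in a fixed order, each recomputed on the
survivors of the previous step.  The HWE exact test is the two-sided
probability-mass-ordering conditional test, evaluated on founders only so
that family relatedness does not inflate the statistic.

Also provided: assignment of subjects to the APOE strata E2 (e2e2/e2e3),
E3 (e3e3) and E4 (e3e4/e4e4) from the rs429358/rs7412 genotype pair
(e2e4 carriers and implausible/missing genotype pairs are excluded), and
alignment of every SNP's effect allele to the pooled-sample minor allele
so that per-stratum effect estimates are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree, StratumAssignment, MISSING_PARENT

__all__ = [
    "QcThresholds",
    "QcMetrics",
    "compute_qc_metrics",
    "hwe_exact_test",
    "mendel_error_rates",
    "apply_qc",
    "assign_apoe_groups",
    "align_effect_alleles",
]


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class QcThresholds:
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    missing_max: float = 0.05
    mendel_max: float = 0.02
    hwe_founders_only: bool = True


@dataclass
class QcMetrics:
    maf: pd.Series
    hwe_p: pd.Series
    snp_missing_rate: pd.Series
    subject_missing_rate: pd.Series
    mendel_rate_snp: pd.Series
    mendel_rate_subject: pd.Series
    mendel_rate_family: pd.Series
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------

def minor_allele_frequencies(g: GenotypeMatrix, folded: bool = True) -> pd.Series:
    """Allele frequency per SNP among non-missing calls.

    ``folded=True`` (the QC convention) returns the minor allele frequency
    min(f, 1-f); ``folded=False`` returns the frequency of the coded
    allele as-is, which :func:`align_effect_alleles` needs to decide flips.
    """
    d = g.dosage
    n_called = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * n_called)
        freq[n_called == 0] = np.nan
    if folded:
        freq = np.minimum(freq, 1.0 - freq)
    return pd.Series(freq, index=g.snp_ids, name="maf")


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given the observed genotype counts, conditions on the allele counts and
    sums the probabilities of every heterozygote count (same parity) whose
    conditional probability does not exceed that of the observed table.
    Returns the two-sided p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise QcError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise QcError("at least one genotyped subject required")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    if n_minor == 0:
        return 1.0
    # log P(het = h | allele counts) up to a shared constant:
    #   P(h) propto 2^h * n! / (h! * ((n_minor-h)/2)! * ((n_major-h... )/2)!)
    from scipy.special import gammaln

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    valid = hom_maj >= 0
    hets, hom_min, hom_maj = hets[valid], hom_min[valid], hom_maj[valid]
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    if n_het not in hets:
        raise QcError(f"heterozygote count {n_het} incompatible with allele counts")
    p_obs = prob[np.searchsorted(hets, n_het)]
    p = float(prob[prob <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_pvalues(g: GenotypeMatrix, subjects_mask: np.ndarray | None = None) -> pd.Series:
    d = g.dosage if subjects_mask is None else g.dosage[subjects_mask]
    out = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                int((col == 2).sum()))
    return pd.Series(out, index=g.snp_ids, name="hwe_p")


# ---------------------------------------------------------------------------
# Mendel errors
# ---------------------------------------------------------------------------

def _trio_error(f: float, m: float, c: float) -> bool:
    """Impossible transmission for a biallelic SNP, parents (f, m), child c."""
    fa = {0.0: (0,), 1.0: (0, 1), 2.0: (1,)}
    return not any(a + b == c for a in fa[f] for b in fa[m])


def _duo_error(p: float, c: float) -> bool:
    return (p == 0.0 and c == 2.0) or (p == 2.0 and c == 0.0)


def _trio_error_vec(f: np.ndarray, m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized trio rule over SNPs (same logic as :func:`_trio_error`)."""
    return (
        ((c == 0) & ((f == 2) | (m == 2)))
        | ((c == 2) & ((f == 0) | (m == 0)))
        | ((c == 1) & (((f == 0) & (m == 0)) | ((f == 2) & (m == 2))))
    )


def _duo_error_vec(p: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((p == 0) & (c == 2)) | ((p == 2) & (c == 0))


def mendel_error_rates(g: GenotypeMatrix, ped: Pedigree
                       ) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Mendel error rates per SNP, per subject (as offspring) and per family.

    For every offspring with at least one genotyped parent at a SNP, one
    informative test is counted: the trio rule when both parents are called,
    the duo rule otherwise.  Rates are errors / informative tests for each
    margin; empty denominators yield rate 0.
    """
    sub_idx = {s: i for i, s in enumerate(g.subjects)}
    S = g.n_snps
    err_snp = np.zeros(S)
    n_snp = np.zeros(S)
    err_subj = pd.Series(0.0, index=g.subjects)
    n_subj = pd.Series(0.0, index=g.subjects)
    fam_ids = sorted(set(ped.records["family_id"]))
    err_fam = pd.Series(0.0, index=fam_ids)
    n_fam = pd.Series(0.0, index=fam_ids)

    D = g.dosage
    for _, row in ped.records.iterrows():
        child = row.individual_id
        if child not in sub_idx:
            continue
        parents = [p for p in (row.father_id, row.mother_id)
                   if p != MISSING_PARENT and p in sub_idx]
        if not parents:
            continue
        ci = sub_idx[child]
        c = D[ci]
        c_ok = ~np.isnan(c)
        pvals = [D[sub_idx[p]] for p in parents]
        p_ok = [~np.isnan(pv) for pv in pvals]
        if len(pvals) == 2:
            both = c_ok & p_ok[0] & p_ok[1]
            one_f = c_ok & p_ok[0] & ~p_ok[1]
            one_m = c_ok & ~p_ok[0] & p_ok[1]
            err = np.zeros(S, dtype=bool)
            err[both] = _trio_error_vec(pvals[0][both], pvals[1][both], c[both])
            err[one_f] = _duo_error_vec(pvals[0][one_f], c[one_f])
            err[one_m] = _duo_error_vec(pvals[1][one_m], c[one_m])
            informative = both | one_f | one_m
        else:
            informative = c_ok & p_ok[0]
            err = np.zeros(S, dtype=bool)
            err[informative] = _duo_error_vec(pvals[0][informative],
                                              c[informative])
        n_inf = int(informative.sum())
        n_err = int(err.sum())
        n_snp += informative
        err_snp += err
        n_subj[child] += n_inf
        err_subj[child] += n_err
        n_fam[row.family_id] += n_inf
        err_fam[row.family_id] += n_err

    def rate(e, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(np.asarray(n) > 0, np.asarray(e) / np.asarray(n), 0.0)
        return r

    return (
        pd.Series(rate(err_snp, n_snp), index=g.snp_ids, name="mendel_rate_snp"),
        pd.Series(rate(err_subj.to_numpy(), n_subj.to_numpy()), index=g.subjects,
                  name="mendel_rate_subject"),
        pd.Series(rate(err_fam.to_numpy(), n_fam.to_numpy()), index=fam_ids,
                  name="mendel_rate_family"),
    )


# ---------------------------------------------------------------------------
# aggregate metrics / filtering
# ---------------------------------------------------------------------------

def compute_qc_metrics(g: GenotypeMatrix, ped: Pedigree,
                       hwe_founders_only: bool = True) -> QcMetrics:
    if not set(g.subjects) <= set(ped.individual_ids):
        raise QcError("genotyped subjects must all appear in the pedigree")
    d = g.dosage
    snp_missing = pd.Series(np.isnan(d).mean(axis=0), index=g.snp_ids)
    subj_missing = pd.Series(np.isnan(d).mean(axis=1), index=g.subjects)
    maf = minor_allele_frequencies(g)
    founders = set(ped.founder_ids)
    mask = np.array([s in founders for s in g.subjects]) if hwe_founders_only else None
    if mask is not None and mask.sum() == 0:
        mask = None
    hwe = hwe_pvalues(g, mask)
    m_snp, m_subj, m_fam = mendel_error_rates(g, ped)
    flags = {"maf_undefined": list(maf.index[maf.isna()])}
    return QcMetrics(maf, hwe, snp_missing, subj_missing, m_snp, m_subj, m_fam, flags)


def apply_qc(g: GenotypeMatrix, ped: Pedigree,
             thresholds: QcThresholds | None = None
             ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the QC filters in fixed order, recomputing metrics each step.

    Order: subject missingness -> SNP missingness -> MAF -> HWE ->
    Mendel (SNP) -> Mendel (subject) -> Mendel (family).  Returns the
    filtered matrix and a report with one row per step.
    """
    t = thresholds or QcThresholds()
    report_rows = []
    cur = g

    def drop_subjects(ids, step, criterion, threshold):
        nonlocal cur
        keep = [s for s in cur.subjects if s not in set(ids)]
        report_rows.append((step, criterion, threshold, len(ids),
                            ";".join(map(str, sorted(ids)))))
        if ids:
            cur = cur.subset_subjects(keep)

    def drop_snps(ids, step, criterion, threshold):
        nonlocal cur
        keep = [s for s in cur.snp_ids if s not in set(ids)]
        report_rows.append((step, criterion, threshold, len(ids),
                            ";".join(map(str, sorted(ids)))))
        if not keep:
            raise QcError("all SNPs removed during QC")
        if ids:
            cur = cur.subset_snps(keep)

    miss_subj = pd.Series(np.isnan(cur.dosage).mean(axis=1), index=cur.subjects)
    drop_subjects(list(miss_subj.index[miss_subj > t.missing_max]),
                  "subject_missing", "missing_rate", t.missing_max)

    miss_snp = pd.Series(np.isnan(cur.dosage).mean(axis=0), index=cur.snp_ids)
    drop_snps(list(miss_snp.index[miss_snp > t.missing_max]),
              "snp_missing", "missing_rate", t.missing_max)

    maf = minor_allele_frequencies(cur)
    drop_snps(list(maf.index[(maf < t.maf_min) | maf.isna()]),
              "maf", "maf_min", t.maf_min)

    founders = set(ped.founder_ids)
    mask = np.array([s in founders for s in cur.subjects]) if t.hwe_founders_only else None
    if mask is not None and mask.sum() == 0:
        mask = None
    hwe = hwe_pvalues(cur, mask)
    drop_snps(list(hwe.index[hwe < t.hwe_p_min]), "hwe", "hwe_p_min", t.hwe_p_min)

    m_snp, m_subj, m_fam = mendel_error_rates(cur, ped)
    drop_snps(list(m_snp.index[m_snp > t.mendel_max]),
              "mendel_snp", "mendel_max", t.mendel_max)

    m_snp, m_subj, m_fam = mendel_error_rates(cur, ped)
    drop_subjects(list(m_subj.index[m_subj > t.mendel_max]),
                  "mendel_subject", "mendel_max", t.mendel_max)

    m_snp, m_subj, m_fam = mendel_error_rates(cur, ped)
    bad_fams = set(m_fam.index[m_fam > t.mendel_max])
    fam_of = ped.records.set_index("individual_id")["family_id"]
    bad_subjects = [s for s in cur.subjects if fam_of.get(s) in bad_fams]
    drop_subjects(bad_subjects, "mendel_family", "mendel_max", t.mendel_max)

    report = pd.DataFrame(report_rows, columns=["step", "criterion", "threshold",
                                                "items_removed", "removed_ids"])
    return cur, report


# ---------------------------------------------------------------------------
# APOE strata
# ---------------------------------------------------------------------------

_HAP_TO_EPS = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4"}
_GROUP_OF = {
    frozenset({"e2"}): "E2", frozenset({"e2", "e3"}): "E2",
    frozenset({"e3"}): "E3",
    frozenset({"e3", "e4"}): "E4", frozenset({"e4"}): "E4",
}


def _classify_pair(g429358: str, g7412: str) -> tuple[str, str]:
    """Map one subject's (rs429358, rs7412) genotype to (stratum, reason)."""
    for gt in (g429358, g7412):
        if set(gt) - {"T", "C"}:
            raise QcError(f"non-T/C allele in APOE genotype {gt!r}")
    a = tuple(g429358)
    b = tuple(g7412)
    diplotypes = set()
    for b_perm in (b, b[::-1]):
        haps = (_HAP_TO_EPS.get((a[0], b_perm[0])), _HAP_TO_EPS.get((a[1], b_perm[1])))
        if None not in haps:
            diplotypes.add(frozenset(haps) if haps[0] != haps[1] else frozenset({haps[0]}))
    if not diplotypes:
        return "excluded", "implausible"
    if frozenset({"e2", "e4"}) in diplotypes:
        # the double heterozygote (TC, CT) phases as e2e4 or e3+invalid;
        # resolved as e2e4 and excluded from the three strata
        return "excluded", "e2e4"
    dip = next(iter(diplotypes))
    return _GROUP_OF[dip], ""


def assign_apoe_groups(rs429358: pd.Series, rs7412: pd.Series) -> StratumAssignment:
    """Assign APOE strata from nucleotide genotype strings (e.g. ``"TC"``).

    rs429358 is the e4-encoding SNP (T/C) and rs7412 the e2-encoding SNP
    (C/T).  Subjects with a missing call at either SNP, an e2e4 diplotype,
    or a genotype pair implying the implausible (C, T) haplotype are
    excluded with a reason code.
    """
    rs429358 = rs429358.astype("string")
    rs7412 = rs7412.reindex(rs429358.index).astype("string")
    labels, reasons = {}, {}
    for subj in rs429358.index:
        g1, g2 = rs429358[subj], rs7412[subj]
        if pd.isna(g1) or pd.isna(g2) or "0" in str(g1) + str(g2):
            labels[subj], reasons[subj] = "excluded", "missing"
            continue
        labels[subj], reasons[subj] = _classify_pair(str(g1), str(g2))
    return StratumAssignment(pd.Series(labels), pd.Series(reasons))


def apoe_genotype_strings(g: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Extract rs429358/rs7412 nucleotide genotype strings from dosages."""
    out = []
    for snp in ("rs429358", "rs7412"):
        if snp not in g.snps.index:
            raise QcError(f"{snp} not present in genotype matrix")
        minor = g.snps.loc[snp, "allele_minor"]
        major = g.snps.loc[snp, "allele_major"]
        d = g.dosage_of(snp)
        vals = pd.Series(
            [("0" if np.isnan(x) else minor * int(x) + major * (2 - int(x)))
             for x in d],
            index=g.subjects,
        )
        out.append(vals)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# effect-allele alignment
# ---------------------------------------------------------------------------

def align_effect_alleles(g: GenotypeMatrix, strata: StratumAssignment
                         ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recode every SNP so the counted allele is the minor allele of the
    pooled (E2 u E3 u E4) sample; ties break to the lexicographically
    smaller allele.  Returns the aligned matrix and a flip log."""
    pooled = strata.subjects_in("pooled")
    pooled = [s for s in pooled if s in g.subjects]
    if not pooled:
        raise QcError("pooled sample is empty; cannot align effect alleles")
    sub = g.subset_subjects(pooled)
    freq = minor_allele_frequencies(sub, folded=False)
    snps = g.snps.copy()
    dosage = g.dosage.copy()
    hap = g.haplotypes.copy() if g.haplotypes is not None else None
    flips = []
    for j, snp in enumerate(g.snp_ids):
        f = freq[snp]
        minor, major = snps.iloc[j]["allele_minor"], snps.iloc[j]["allele_major"]
        flip = False
        if np.isnan(f):
            pass
        elif f > 0.5:
            flip = True
        elif f == 0.5 and minor > major:
            flip = True  # tie: count the lexicographically smaller allele
        if flip:
            dosage[:, j] = 2.0 - dosage[:, j]
            if hap is not None:
                hap[:, :, j] = 1 - hap[:, :, j]
            snps.iloc[j, snps.columns.get_loc("allele_minor")] = major
            snps.iloc[j, snps.columns.get_loc("allele_major")] = minor
        flips.append((snp, flip, float(f) if not np.isnan(f) else np.nan))
    log = pd.DataFrame(flips, columns=["snp_id", "flipped", "pooled_freq_before"])
    return GenotypeMatrix(list(g.subjects), snps, dosage, hap), log
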