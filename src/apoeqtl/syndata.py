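"""Synthetic family cohort generator.

Emulates the statistical structure the stratified association analysis
assumes: nuclear families (~1,800 subjects), a panel of regional SNPs in
LD blocks gene-dropped through the pedigrees (zero Mendel errors by
construction), the two APOE-defining SNPs rs429358/rs7412 with haplotype
frequencies chosen to reproduce the observed E2/E3/E4 group shares,
covariates calibrated to the study cohort's means and SDs, and metabolite
concentrations generated from the stage-one model run forward: log
concentration = intercept + covariate effects + planted stratum-specific
SNP effects + family polygenic effect + residual, exponentiated so all
concentrations are strictly positive.

Everything is deterministic given ``SimConfig.seed``: each operation
derives its own random stream from the seed and a fixed per-operation
salt, so the pieces can be regenerated independently or as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EffectPlan,
    GenotypeMatrix,
    MetabolitePanel,
    Pedigree,
    StratumAssignment,
)
from . import io as _io
from .assoc import pedigree_kinship

__all__ = [
    "SimConfig",
    "HaplotypePool",
    "simulate_pedigrees",
    "simulate_founder_haplotypes",
    "gene_drop",
    "simulate_apoe",
    "simulate_covariates",
    "simulate_metabolites",
    "simulate_cohort",
    "write_fixture",
]


class ConfigError(ValueError):
    pass


# Study-cohort calibration for the continuous covariates: mean (SD).
# TG is simulated log-normal (moment-matched) to keep it positive; all
# others are normal.  Binary covariates are Bernoulli prevalences.
DEFAULT_COVARIATE_PARAMS: dict[str, tuple[float, float]] = {
    "birth_year": (1935.12, 9.66),
    "fbg": (95.97, 20.07),
    "tc": (203.81, 32.63),
    "ldlc": (128.07, 31.61),
    "hdlc": (50.42, 12.95),
    "tg": (119.57, 77.04),
    "bmi": (26.28, 4.38),
    "dbp": (77.36, 7.97),
    "sbp": (122.79, 13.74),
    "egfr": (66.46, 21.54),
}
DEFAULT_BINARY_PARAMS: dict[str, float] = {
    "sex": 0.53,      # fraction female; drawn for offspring, founders are pairs
    "smoking": 0.614,
    "ad": 0.0434,
}
REQUIRED_CONTINUOUS = tuple(DEFAULT_COVARIATE_PARAMS)
REQUIRED_BINARY = tuple(DEFAULT_BINARY_PARAMS)

# 26 genes of the APOE cluster, ordered along the region.
GENE_NAMES = [
    "CEACAM22P", "BCL3", "CBLC", "BCAM", "NECTIN2", "TOMM40", "APOE",
    "APOC1", "APOC1P1", "APOC4", "APOC2", "CLPTM1", "RELB", "CLASRP",
    "ZNF296", "GEMIN7", "PPP1R37", "NKPD1", "TRAPPC6A", "BLOC1S3",
    "EXOC3L2", "MARK4", "CKM", "KLC3", "ERCC2", "RSPH6A",
]

_REGION_START = 44_400_000
_REGION_STEP = 10_000
_APOE_SNPS = {"rs429358": (44_908_684, "C", "T"), "rs7412": (44_908_822, "T", "C")}

# per-operation salts so one seed drives independent, stable streams
_SALT = {"ped": 11, "hap": 23, "drop": 37, "apoe": 53, "cov": 71, "met": 89}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the analyzed cohort: ~1,798 subjects in nuclear
    families, 94 regional SNPs in LD blocks plus the two APOE SNPs, APOE
    haplotype frequencies (0.08, 0.80, 0.12) reproducing the post-exclusion
    group shares, Table-calibrated covariates, and equal genetic/residual
    variance on the log-metabolite scale.
    """

    n_families: int = 452
    family_size_dist: dict = field(
        default_factory=lambda: {"kind": "poisson_plus_one", "lam": 1.0, "max": 4}
    )
    n_snps: int = 94
    ld_block_size: int = 6
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_mutation_rate: float = 0.15
    recomb_rate: float = 0.0
    apoe_hap_freqs: tuple[float, float, float] = (0.08, 0.80, 0.12)
    sigma_g2: float = 0.5
    sigma_e2: float = 0.5
    n_lipid: int = 140
    n_polar: int = 77
    covariate_params: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    binary_params: dict = field(default_factory=lambda: dict(DEFAULT_BINARY_PARAMS))
    covariate_effects: dict = field(
        default_factory=lambda: {"bmi": 0.05, "tg": 0.05}
    )
    apoe_ldlc_shift: dict | None = None  # optional confounding hook, off by default
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within [0.01, 0.5]")
        f = self.apoe_hap_freqs
        if abs(sum(f) - 1.0) > 1e-9:
            raise ConfigError("apoe_hap_freqs must sum to 1")
        if any(x < 0 or x > 1 for x in f):
            raise ConfigError("apoe_hap_freqs must be in [0, 1]")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ConfigError("variance components must be non-negative")

    def rng(self, op: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SALT[op]])


@dataclass
class HaplotypePool:
    """Founder haplotypes over the regional SNPs.

    ``haplotypes``: (H, S) 0/1 minor-allele indicators; ``ld_blocks``
    partitions SNP indices into contiguous blocks (correlated within,
    independent across); ``maf_targets`` are the per-SNP target minor
    allele frequencies.
    """

    haplotypes: np.ndarray
    ld_blocks: list[np.ndarray]
    maf_targets: np.ndarray

    def __post_init__(self):
        H, S = self.haplotypes.shape
        covered = np.concatenate(self.ld_blocks) if self.ld_blocks else np.array([])
        if sorted(covered.tolist()) != list(range(S)):
            raise ConfigError("ld_blocks must partition the SNP indices")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ConfigError("haplotype alleles must be 0/1")


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def _draw_offspring_counts(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist.get("kind", "poisson_plus_one")
    if kind == "fixed":
        return np.full(n, int(dist["k"]))
    if kind == "poisson_plus_one":
        counts = 1 + rng.poisson(float(dist.get("lam", 1.0)), size=n)
        return np.minimum(counts, int(dist.get("max", 4)))
    raise ConfigError(f"unknown family_size_dist kind {kind!r}")


def simulate_pedigrees(config: SimConfig) -> Pedigree:
    """Nuclear families: two founder parents plus offspring drawn from the
    configured family-size distribution."""
    rng = config.rng("ped")
    offspring = _draw_offspring_counts(config.family_size_dist, config.n_families, rng)
    f_female = float(config.binary_params.get("sex", 0.5))
    rows = []
    for k in range(config.n_families):
        fam = f"fam{k:04d}"
        father, mother = f"{fam}_f", f"{fam}_m"
        rows.append((fam, father, "0", "0", "male"))
        rows.append((fam, mother, "0", "0", "female"))
        for i in range(offspring[k]):
            sex = "female" if rng.random() < f_female else "male"
            rows.append((fam, f"{fam}_o{i + 1}", father, mother, sex))
    return Pedigree(pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    ))


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def simulate_founder_haplotypes(config: SimConfig, n_haplotypes: int,
                                maf_targets: np.ndarray | None = None
                                ) -> HaplotypePool:
    """Block-correlated founder haplotypes with exact marginal MAF control.

    Within a block every site thresholds a latent uniform shared by the
    haplotype (a common ancestral haplotype); with probability
    ``ld_mutation_rate`` a site redraws its own uniform ("mutation"),
    decorrelating it.  Marginals are exactly Bernoulli(maf); blocks are
    mutually independent.
    """
    rng = config.rng("hap")
    S = config.n_snps
    if maf_targets is None:
        maf_targets = rng.uniform(*config.maf_range, size=S)
    maf_targets = np.asarray(maf_targets, dtype=float)
    if ((maf_targets <= 0) | (maf_targets >= 1)).any():
        raise ConfigError("maf targets must lie in (0, 1)")
    blocks = [np.arange(i, min(i + config.ld_block_size, S))
              for i in range(0, S, config.ld_block_size)]
    H = np.empty((n_haplotypes, S), dtype=np.int8)
    for block in blocks:
        shared = rng.uniform(size=n_haplotypes)
        for j in block:
            mutate = rng.uniform(size=n_haplotypes) < config.ld_mutation_rate
            u = np.where(mutate, rng.uniform(size=n_haplotypes), shared)
            H[:, j] = (u < maf_targets[j]).astype(np.int8)
    return HaplotypePool(H, blocks, maf_targets)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _transmit(h0: np.ndarray, h1: np.ndarray, rng: np.random.Generator,
              recomb_rate: float) -> np.ndarray:
    pick = int(rng.integers(2))
    gamete = (h0, h1)[pick].copy()
    if recomb_rate > 0 and rng.random() < recomb_rate:
        cut = int(rng.integers(1, len(gamete)))
        other = (h0, h1)[1 - pick]
        gamete[cut:] = other[cut:]
    return gamete


def _drop_haplotypes(pedigree: Pedigree, founder_haps: dict[str, tuple],
                     rng: np.random.Generator, recomb_rate: float) -> dict[str, tuple]:
    """Transmit phased haplotypes down the pedigree (parents before
    children); every non-founder must have both parents present."""
    haps: dict[str, tuple] = dict(founder_haps)
    pending = [r for _, r in pedigree.records.iterrows()
               if r.individual_id not in haps]
    while pending:
        rest = []
        progressed = False
        for row in pending:
            parents = pedigree.parents_of(row.individual_id)
            if len(parents) != 2:
                raise ConfigError(
                    f"offspring {row.individual_id!r} lacks two pedigree parents"
                )
            if all(p in haps for p in parents):
                pat = _transmit(*haps[parents[0]], rng, recomb_rate)
                mat = _transmit(*haps[parents[1]], rng, recomb_rate)
                haps[row.individual_id] = (pat, mat)
                progressed = True
            else:
                rest.append(row)
        if not progressed:
            raise ConfigError("pedigree cannot be ordered for gene dropping")
        pending = rest
    return haps


def gene_drop(pedigree: Pedigree, pool: HaplotypePool, config: SimConfig
              ) -> GenotypeMatrix:
    """Drop the regional founder haplotypes through the pedigree.

    Founders consume two pool haplotypes each (in pedigree order); every
    offspring receives one randomly chosen haplotype from each parent.
    With the default ``recomb_rate = 0`` the ~1 Mb region is transmitted
    intact, and the construction guarantees zero Mendel errors.
    """
    founders = list(pedigree.founder_ids)
    if pool.haplotypes.shape[0] < 2 * len(founders):
        raise ConfigError(
            f"pool has {pool.haplotypes.shape[0]} haplotypes; "
            f"{2 * len(founders)} needed for {len(founders)} founders"
        )
    rng = config.rng("drop")
    founder_haps = {
        iid: (pool.haplotypes[2 * i].copy(), pool.haplotypes[2 * i + 1].copy())
        for i, iid in enumerate(founders)
    }
    haps = _drop_haplotypes(pedigree, founder_haps, rng, config.recomb_rate)
    ids = list(pedigree.individual_ids)
    hap_arr = np.stack([np.stack(haps[i]) for i in ids])  # (n, 2, S)
    dosage = hap_arr.sum(axis=1).astype(float)
    S = config.n_snps
    snps = pd.DataFrame(
        {
            "chrom": "19",
            "pos": _REGION_START + _REGION_STEP * np.arange(S),
            "allele_minor": "A",
            "allele_major": "G",
            "gene_label": [GENE_NAMES[min(j * len(GENE_NAMES) // S,
                                          len(GENE_NAMES) - 1)] for j in range(S)],
        },
        index=pd.Index([f"snp{j + 1:03d}" for j in range(S)], name="snp_id"),
    )
    return GenotypeMatrix(ids, snps, dosage, hap_arr)


# ---------------------------------------------------------------------------
# APOE SNPs
# ---------------------------------------------------------------------------

def simulate_apoe(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop the two APOE-defining SNPs.

    Founder APOE haplotypes are drawn as e2 = (rs429358-T, rs7412-T),
    e3 = (T, C), e4 = (C, C) with ``apoe_hap_freqs``; the minor alleles are
    C for rs429358 (counts e4 haplotypes) and T for rs7412 (counts e2).
    """
    rng = config.rng("apoe")
    founders = list(pedigree.founder_ids)
    eps = rng.choice(3, size=(len(founders), 2), p=list(config.apoe_hap_freqs))
    # per-haplotype minor-allele indicators: [rs429358 (minor C), rs7412 (minor T)]
    code = np.array([[0, 1], [0, 0], [1, 0]], dtype=np.int8)  # rows: e2, e3, e4
    founder_haps = {
        iid: (code[eps[i, 0]].copy(), code[eps[i, 1]].copy())
        for i, iid in enumerate(founders)
    }
    haps = _drop_haplotypes(pedigree, founder_haps, rng, recomb_rate=0.0)
    ids = list(pedigree.individual_ids)
    hap_arr = np.stack([np.stack(haps[i]) for i in ids])
    dosage = hap_arr.sum(axis=1).astype(float)
    meta = pd.DataFrame(
        {
            "chrom": "19",
            "pos": [_APOE_SNPS[s][0] for s in ("rs429358", "rs7412")],
            "allele_minor": [_APOE_SNPS[s][1] for s in ("rs429358", "rs7412")],
            "allele_major": [_APOE_SNPS[s][2] for s in ("rs429358", "rs7412")],
            "gene_label": "APOE",
        },
        index=pd.Index(["rs429358", "rs7412"], name="snp_id"),
    )
    return GenotypeMatrix(ids, meta, dosage, hap_arr)


def combine_genotypes(regional: GenotypeMatrix, apoe: GenotypeMatrix
                      ) -> GenotypeMatrix:
    """Merge the regional panel and the APOE SNPs, sorted by position."""
    if list(regional.subjects) != list(apoe.subjects):
        raise ConfigError("subject order mismatch between genotype sets")
    snps = pd.concat([regional.snps, apoe.snps]).sort_values(["chrom", "pos"])
    dosage = np.concatenate([regional.dosage, apoe.dosage], axis=1)
    haps = np.concatenate([regional.haplotypes, apoe.haplotypes], axis=2)
    all_ids = list(regional.snp_ids) + list(apoe.snp_ids)
    order = [all_ids.index(s) for s in snps.index]
    return GenotypeMatrix(list(regional.subjects), snps,
                          dosage[:, order], haps[:, :, order])


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(pedigree: Pedigree, config: SimConfig,
                        strata: StratumAssignment | None = None) -> pd.DataFrame:
    """Covariate table calibrated to the study cohort.

    ``sex`` (1 = female) comes from the pedigree; continuous covariates are
    normal with the configured mean/SD except TG, which is log-normal with
    matched moments; binary covariates are Bernoulli.  Independent of
    genotype unless the ``apoe_ldlc_shift`` confounding hook is enabled
    (a per-stratum additive shift of LDL-C).
    """
    missing = set(REQUIRED_CONTINUOUS) - set(config.covariate_params)
    if missing:
        raise ConfigError(f"covariate_params missing: {sorted(missing)}")
    missing_b = set(REQUIRED_BINARY) - set(config.binary_params)
    if missing_b:
        raise ConfigError(f"binary_params missing: {sorted(missing_b)}")
    rng = config.rng("cov")
    ids = list(pedigree.individual_ids)
    n = len(ids)
    out = pd.DataFrame(index=pd.Index(ids, name="subject"))
    out["sex"] = [1.0 if pedigree.sex_of(i) == "female" else 0.0 for i in ids]
    for name in ("smoking", "ad"):
        out[name] = (rng.uniform(size=n) < config.binary_params[name]).astype(float)
    for name, (mean, sd) in config.covariate_params.items():
        if name == "tg" and sd > 0:
            s2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - s2 / 2.0
            out[name] = rng.lognormal(mu, np.sqrt(s2), size=n)
        else:
            out[name] = rng.normal(mean, sd, size=n)
    if config.apoe_ldlc_shift and strata is not None:
        shift = strata.labels.map(config.apoe_ldlc_shift).fillna(0.0)
        out["ldlc"] = out["ldlc"] + shift.reindex(out.index).fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def simulate_metabolites(genotypes: GenotypeMatrix, covariates: pd.DataFrame,
                         strata: StratumAssignment, plan: EffectPlan,
                         config: SimConfig, pedigree: Pedigree
                         ) -> MetabolitePanel:
    """Generate the metabolite panel from the stage-one model run forward.

    For each analyte, the log concentration is an intercept plus small
    effects of standardized covariates, plus the planted per-stratum SNP
    effects (dosage x beta for the subject's stratum), plus a family
    polygenic effect u ~ N(0, sigma_g2 * 2Phi) drawn per family, plus an
    i.i.d. N(0, sigma_e2) residual.  Concentrations are exp(log value),
    hence strictly positive.
    """
    for snp in set(plan.entries["snp_id"]):
        if snp not in genotypes.snps.index:
            raise ConfigError(f"effect plan references unknown SNP {snp!r}")
    rng = config.rng("met")
    ids = list(genotypes.subjects)
    n = len(ids)
    names = ([f"lipid_{i + 1:03d}" for i in range(config.n_lipid)]
             + [f"polar_{i + 1:03d}" for i in range(config.n_polar)])
    classes = {m: ("lipid" if m.startswith("lipid") else "polar") for m in names}
    for met in set(plan.entries["metabolite_id"]):
        if met not in classes:
            raise ConfigError(f"effect plan references unknown metabolite {met!r}")

    # covariate contribution, shared across analytes (z-scored covariates)
    cov_term = np.zeros(n)
    cov = covariates.reindex(ids)
    for name, eff in config.covariate_effects.items():
        col = cov[name].to_numpy(float)
        sd = col.std(ddof=0)
        if sd > 0:
            cov_term = cov_term + eff * (col - col.mean()) / sd

    # family polygenic effects: one Cholesky per family block, reused for
    # all analytes (fresh draws per analyte)
    kin = pedigree_kinship(pedigree).subset(ids)
    fam_of = pedigree.records.set_index("individual_id")["family_id"]
    blocks = []
    pos = {s: i for i, s in enumerate(ids)}
    for _, members in pd.Series(ids).groupby([fam_of.get(s) for s in ids]):
        idx = np.array([pos[s] for s in members])
        block = kin.values[np.ix_(idx, idx)]
        L = np.linalg.cholesky(block + 1e-10 * np.eye(len(idx)))
        blocks.append((idx, L))

    labels = strata.labels.reindex(ids)
    M = config.n_lipid + config.n_polar
    log_vals = np.empty((n, M))
    sg = np.sqrt(config.sigma_g2)
    se = np.sqrt(config.sigma_e2)
    plan_by_met: dict[str, list] = {}
    for _, e in plan.entries.iterrows():
        plan_by_met.setdefault(e.metabolite_id, []).append(e)
    for m_idx, met in enumerate(names):
        y = cov_term.copy()
        for e in plan_by_met.get(met, ()):
            dos = genotypes.dosage_of(e.snp_id)
            dos = np.where(np.isnan(dos), 0.0, dos)
            if e.stratum == "all":
                y = y + e.beta_true * dos
            else:
                in_stratum = (labels == e.stratum).to_numpy()
                y = y + np.where(in_stratum, e.beta_true * dos, 0.0)
        if sg > 0:
            u = np.zeros(n)
            for idx, L in blocks:
                u[idx] = sg * (L @ rng.standard_normal(len(idx)))
            y = y + u
        y = y + se * rng.standard_normal(n)
        log_vals[:, m_idx] = y
    values = pd.DataFrame(np.exp(log_vals), index=pd.Index(ids, name="subject"),
                          columns=names)
    return MetabolitePanel(values, classes)


# ---------------------------------------------------------------------------
# whole-cohort convenience + fixture writing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # regional + APOE SNPs, phased
    covariates: pd.DataFrame
    strata: StratumAssignment
    metabolites: MetabolitePanel
    plan: EffectPlan


def simulate_cohort(config: SimConfig, plan: EffectPlan | None = None
                    ) -> SimulatedCohort:
    """Run every simulation stage in order and return the assembled cohort."""
    from .gqc import assign_apoe_groups, apoe_genotype_strings

    plan = plan if plan is not None else EffectPlan()
    ped = simulate_pedigrees(config)
    n_founders = int(ped.founder_mask.sum())
    pool = simulate_founder_haplotypes(config, 2 * n_founders)
    regional = gene_drop(ped, pool, config)
    apoe = simulate_apoe(ped, config)
    genotypes = combine_genotypes(regional, apoe)
    g429358, g7412 = apoe_genotype_strings(genotypes)
    strata = assign_apoe_groups(g429358, g7412)
    covariates = simulate_covariates(ped, config, strata)
    metabolites = simulate_metabolites(genotypes, covariates, strata, plan,
                                       config, ped)
    return SimulatedCohort(config, ped, genotypes, covariates, strata,
                           metabolites, plan)


def write_fixture(outdir: str | Path, cohort: SimulatedCohort) -> dict[str, Path]:
    """Write the full fixture: PLINK text .ped/.map, covariates/metabolites/
    annotation TSVs and the ground-truth effect plan.  Round-trips
    losslessly through the readers in :mod:`apoeqtl.io`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "cohort.ped",
        "map": outdir / "cohort.map",
        "annotation": outdir / "annotation.tsv",
        "covariates": outdir / "covariates.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "classes": outdir / "metabolite_classes.tsv",
        "truth": outdir / "truth.tsv",
    }
    _io.write_ped_map(outdir / "cohort", cohort.pedigree, cohort.genotypes)
    _io.write_annotation(paths["annotation"], cohort.genotypes)
    _io.write_covariates(paths["covariates"], cohort.covariates)
    _io.write_metabolites(paths["metabolites"], paths["classes"],
                          cohort.metabolites)
    _io.write_effect_plan(paths["truth"], cohort.plan)
    return paths
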