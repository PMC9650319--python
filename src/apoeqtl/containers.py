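"""Core in-memory containers shared across the analysis stages.

The pipeline moves five kinds of objects around: a pedigree, a genotype
matrix (minor-allele dosages plus optional phased haplotypes), a kinship
matrix, a metabolite panel and a covariate table.  All are thin, validated
wrappers over pandas/numpy structures so that every stage can rely on the
same invariants (unique subject ids, dosages in {0, 1, 2, NaN}, symmetric
kinship, strictly positive metabolite concentrations on the raw scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "KinshipMatrix",
    "MetabolitePanel",
    "CovariateTable",
    "StratumAssignment",
    "EffectPlan",
]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad parent reference, cycle...)."""


class Pedigree:
    """Family structure: one record per individual.

    Parameters
    ----------
    records : DataFrame
        Columns ``family_id``, ``individual_id``, ``father_id``,
        ``mother_id``, ``sex``.  Missing parents are coded ``"0"`` (PLINK
        convention); ``sex`` is ``"male"``/``"female"``.

    Invariants enforced on construction: individual ids unique across the
    cohort, a non-missing parent id refers to a record in the same family,
    founders have both parents missing, and no individual is its own
    ancestor.
    """

    REQUIRED = ("family_id", "individual_id", "father_id", "mother_id", "sex")

    def __init__(self, records: pd.DataFrame):
        missing = set(self.REQUIRED) - set(records.columns)
        if missing:
            raise PedigreeError(f"pedigree is missing columns: {sorted(missing)}")
        df = records.loc[:, list(self.REQUIRED)].copy()
        for col in ("family_id", "individual_id", "father_id", "mother_id"):
            df[col] = df[col].astype(str)
        df[["father_id", "mother_id"]] = df[["father_id", "mother_id"]].replace(
            {"nan": MISSING_PARENT, "None": MISSING_PARENT, "": MISSING_PARENT}
        )
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise PedigreeError(f"duplicate individual id: {dup!r}")
        bad_sex = set(df["sex"]) - {"male", "female"}
        if bad_sex:
            raise PedigreeError(f"invalid sex codes: {sorted(bad_sex)}")
        self.records = df.reset_index(drop=True)
        self._by_id = self.records.set_index("individual_id")
        self._validate_parents()
        self._validate_acyclic()

    def _validate_parents(self) -> None:
        by_id = self._by_id
        for _, row in self.records.iterrows():
            has_f = row.father_id != MISSING_PARENT
            has_m = row.mother_id != MISSING_PARENT
            if has_f != has_m:
                raise PedigreeError(
                    f"individual {row.individual_id!r} has exactly one parent; "
                    "founders must have both parents missing"
                )
            for pid in (row.father_id, row.mother_id):
                if pid == MISSING_PARENT:
                    continue
                if pid not in by_id.index:
                    raise PedigreeError(
                        f"parent {pid!r} of {row.individual_id!r} not in pedigree"
                    )
                if by_id.loc[pid, "family_id"] != row.family_id:
                    raise PedigreeError(
                        f"parent {pid!r} of {row.individual_id!r} is in a "
                        "different family"
                    )

    def _validate_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise PedigreeError(f"pedigree cycle involving {iid!r}")
            state[iid] = 0
            for pid in self.parents_of(iid):
                visit(pid)
            state[iid] = 1

        for iid in self.records["individual_id"]:
            visit(iid)

    # -- accessors -------------------------------------------------------
    @property
    def individual_ids(self) -> pd.Index:
        return pd.Index(self.records["individual_id"])

    @property
    def n_individuals(self) -> int:
        return len(self.records)

    def parents_of(self, iid: str) -> tuple[str, ...]:
        row = self._by_id.loc[iid]
        return tuple(
            p for p in (row["father_id"], row["mother_id"]) if p != MISSING_PARENT
        )

    def is_founder(self, iid: str) -> bool:
        return len(self.parents_of(iid)) == 0

    @property
    def founder_mask(self) -> np.ndarray:
        return (
            (self.records["father_id"] == MISSING_PARENT)
            & (self.records["mother_id"] == MISSING_PARENT)
        ).to_numpy()

    @property
    def founder_ids(self) -> pd.Index:
        return pd.Index(self.records.loc[self.founder_mask, "individual_id"])

    def families(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.records.groupby("family_id", sort=False)

    def sex_of(self, iid: str) -> str:
        return self._by_id.loc[iid, "sex"]

    def family_of(self, iid: str) -> str:
        return self._by_id.loc[iid, "family_id"]

    def subset(self, individual_ids: Sequence[str]) -> "Pedigree":
        """Restrict to the given individuals, dropping parent links that
        point outside the subset (kept individuals become founders)."""
        keep = set(map(str, individual_ids))
        df = self.records[self.records["individual_id"].isin(keep)].copy()
        for col in ("father_id", "mother_id"):
            df.loc[~df[col].isin(keep), col] = MISSING_PARENT
        return Pedigree(df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.records.equals(other.records)


class GenotypeError(ValueError):
    pass


class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with SNP metadata.

    ``dosage[i, j]`` counts copies of ``allele_minor`` of SNP ``j`` carried
    by subject ``i`` (0/1/2, NaN for a missing call).  ``haplotypes`` is an
    optional phased ``(n, 2, S)`` int8 array of per-haplotype minor-allele
    indicators (-1 for missing) kept by the simulator so that LD can be
    computed from true phase.
    """

    def __init__(
        self,
        subjects: Sequence[str],
        snps: pd.DataFrame,
        dosage: np.ndarray,
        haplotypes: np.ndarray | None = None,
    ):
        self.subjects = pd.Index([str(s) for s in subjects], name="subject")
        if self.subjects.has_duplicates:
            raise GenotypeError("duplicate subject ids")
        required = {"chrom", "pos", "allele_minor", "allele_major"}
        if not required <= set(snps.columns):
            raise GenotypeError(f"snps table needs columns {sorted(required)}")
        snps = snps.copy()
        if "gene_label" not in snps.columns:
            snps["gene_label"] = "unassigned"
        self.snps = snps
        if (snps["allele_minor"] == snps["allele_major"]).any():
            raise GenotypeError("allele_minor must differ from allele_major")
        for _, grp in snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError("positions must be strictly increasing per chromosome")
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(self.subjects), len(snps)):
            raise GenotypeError(
                f"dosage shape {dosage.shape} does not match "
                f"({len(self.subjects)}, {len(snps)})"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeError("dosage values must be in {0, 1, 2} or NaN")
        self.dosage = dosage
        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes)
            if haplotypes.shape != (len(self.subjects), 2, len(snps)):
                raise GenotypeError("haplotypes shape must be (n, 2, S)")
        self.haplotypes = haplotypes

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps.index)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosage_of(self, snp_id: str) -> np.ndarray:
        j = self.snps.index.get_loc(snp_id)
        return self.dosage[:, j]

    def subset_subjects(self, subjects: Sequence[str]) -> "GenotypeMatrix":
        idx = self.subjects.get_indexer([str(s) for s in subjects])
        if (idx < 0).any():
            raise GenotypeError("unknown subject in subset request")
        hap = self.haplotypes[idx] if self.haplotypes is not None else None
        return GenotypeMatrix(
            [self.subjects[i] for i in idx], self.snps, self.dosage[idx], hap
        )

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.snps.index.get_loc(s) for s in snp_ids]
        hap = self.haplotypes[:, :, cols] if self.haplotypes is not None else None
        return GenotypeMatrix(
            list(self.subjects), self.snps.iloc[cols], self.dosage[:, cols], hap
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.subjects, columns=self.snp_ids)


class KinshipMatrix:
    """Expected relationship matrix (2 x kinship coefficient)."""

    def __init__(self, subjects: Sequence[str], values: np.ndarray):
        self.subjects = pd.Index([str(s) for s in subjects], name="subject")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.subjects),) * 2:
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = (values + values.T) / 2.0

    def subset(self, subjects: Sequence[str]) -> "KinshipMatrix":
        idx = self.subjects.get_indexer([str(s) for s in subjects])
        if (idx < 0).any():
            raise ValueError("unknown subject in kinship subset")
        return KinshipMatrix(
            [self.subjects[i] for i in idx], self.values[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.subjects)


class MetabolitePanel:
    """Subjects x metabolites concentration table with lipid/polar labels."""

    def __init__(self, values: pd.DataFrame, classes: Mapping[str, str] | pd.Series):
        self.values = values.copy()
        self.values.index = self.values.index.astype(str)
        classes = pd.Series(dict(classes) if not isinstance(classes, pd.Series) else classes)
        classes = classes.reindex(self.values.columns)
        if classes.isna().any():
            missing = list(classes.index[classes.isna()])
            raise ValueError(f"metabolites without class label: {missing[:5]}")
        bad = set(classes) - {"lipid", "polar"}
        if bad:
            raise ValueError(f"metabolite classes must be lipid/polar, got {bad}")
        self.classes = classes

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def subjects(self) -> pd.Index:
        return self.values.index


CovariateTable = pd.DataFrame  # subjects x covariates; binary columns 0/1


STRATA = ("E2", "E3", "E4")


@dataclass
class StratumAssignment:
    """APOE stratum per subject, with exclusion reason codes."""

    labels: pd.Series  # subject -> E2/E3/E4/excluded
    reasons: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        bad = set(self.labels) - {"E2", "E3", "E4", "excluded"}
        if bad:
            raise ValueError(f"invalid stratum labels: {sorted(bad)}")
        if self.reasons is None:
            self.reasons = pd.Series("", index=self.labels.index)

    def subjects_in(self, stratum: str) -> pd.Index:
        if stratum == "pooled":
            return self.labels.index[self.labels.isin(STRATA)]
        return self.labels.index[self.labels == stratum]

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(
            ["E2", "E3", "E4", "excluded"], fill_value=0
        )


class EffectPlan:
    """Planted ground-truth stratum-specific SNP effects on log concentration.

    One row per (snp_id, metabolite_id, stratum) with the per-minor-allele
    effect ``beta_true``; ``stratum == "all"`` plants the same effect in
    every stratum and may not coexist with stratum-specific rows for the
    same (snp, metabolite).
    """

    COLUMNS = ("snp_id", "metabolite_id", "stratum", "beta_true")

    def __init__(self, entries: pd.DataFrame | None = None):
        if entries is None or len(entries) == 0:
            entries = pd.DataFrame(columns=list(self.COLUMNS))
        entries = entries.loc[:, list(self.COLUMNS)].copy()
        entries["beta_true"] = entries["beta_true"].astype(float)
        keys = entries[["snp_id", "metabolite_id", "stratum"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (snp, metabolite, stratum) in effect plan")
        bad = set(entries["stratum"]) - {"E2", "E3", "E4", "all"}
        if bad:
            raise ValueError(f"invalid strata in effect plan: {sorted(bad)}")
        for (snp, met), grp in entries.groupby(["snp_id", "metabolite_id"]):
            if "all" in set(grp["stratum"]) and len(grp) > 1:
                raise ValueError(
                    f"effect plan mixes 'all' with stratum-specific entries "
                    f"for ({snp}, {met})"
                )
        self.entries = entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def beta_for(self, snp_id: str, metabolite_id: str, stratum: str) -> float:
        e = self.entries
        hit = e[(e.snp_id == snp_id) & (e.metabolite_id == metabolite_id)]
        if len(hit) == 0:
            return 0.0
        allrow = hit[hit.stratum == "all"]
        if len(allrow):
            return float(allrow["beta_true"].iloc[0])
        row = hit[hit.stratum == stratum]
        return float(row["beta_true"].iloc[0]) if len(row) else 0.0
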