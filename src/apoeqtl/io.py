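"""Readers and writers for the plain-text interchange formats.

Genotypes travel as PLINK text ``.ped``/``.map`` pairs (white-space
delimited, alleles as nucleotide letters, ``0`` = missing) or as a TSV
dosage matrix; everything else is tab-delimited TSV with a header row and
``NA`` for missing values.  A SNP annotation table (snp_id, chrom, pos,
minor/major allele, gene label) pins down the allele coding so that a
written fixture round-trips to an identical dosage matrix even when the
realized minor allele differs from the nominal one.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EffectPlan,
    GenotypeMatrix,
    MetabolitePanel,
    Pedigree,
    MISSING_PARENT,
)

NA = "NA"
_SEX_TO_PED = {"male": "1", "female": "2"}
_PED_TO_SEX = {"1": "male", "2": "female"}


class IoError(OSError):
    pass


# ---------------------------------------------------------------------------
# pedigree (.fam style)
# ---------------------------------------------------------------------------

def write_fam(path: str | os.PathLike, pedigree: Pedigree) -> None:
    rows = []
    for _, r in pedigree.records.iterrows():
        rows.append(
            [r.family_id, r.individual_id, r.father_id, r.mother_id,
             _SEX_TO_PED[r.sex], "-9"]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_fam(path: str | os.PathLike) -> Pedigree:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 5:
        raise IoError(f"{path}: expected at least 5 .fam columns")
    df = df.iloc[:, :5]
    df.columns = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
    df["sex"] = df["sex"].map(_PED_TO_SEX)
    if df["sex"].isna().any():
        raise IoError(f"{path}: sex codes must be 1 (male) or 2 (female)")
    return Pedigree(df)


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

def write_ped_map(prefix: str | os.PathLike, pedigree: Pedigree,
                  genotypes: GenotypeMatrix) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map``.

    Subjects absent from the genotype matrix get all-missing calls.
    """
    prefix = Path(prefix)
    snps = genotypes.snps
    map_df = pd.DataFrame(
        {
            "chrom": snps["chrom"].to_numpy(),
            "snp_id": snps.index.to_numpy(),
            "cm": 0,
            "pos": snps["pos"].to_numpy(),
        }
    )
    map_df.to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)

    minor = snps["allele_minor"].to_numpy()
    major = snps["allele_major"].to_numpy()
    lines = []
    for _, r in pedigree.records.iterrows():
        fields = [r.family_id, r.individual_id, r.father_id, r.mother_id,
                  _SEX_TO_PED[r.sex], "-9"]
        if r.individual_id in genotypes.subjects:
            i = genotypes.subjects.get_loc(r.individual_id)
            d = genotypes.dosage[i]
            for j in range(genotypes.n_snps):
                if np.isnan(d[j]):
                    fields += ["0", "0"]
                else:
                    k = int(d[j])
                    fields += [minor[j]] * k + [major[j]] * (2 - k)
        else:
            fields += ["0", "0"] * genotypes.n_snps
        lines.append(" ".join(map(str, fields)))
    prefix.with_suffix(".ped").write_text("\n".join(lines) + "\n")


def read_ped_map(prefix: str | os.PathLike,
                 annotation: pd.DataFrame | None = None
                 ) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a PLINK text fileset back into (Pedigree, GenotypeMatrix).

    Without ``annotation`` the minor allele is the less frequent observed
    allele (lexicographic tie-break); with it, the coding in the annotation
    table is used verbatim, making write -> read lossless.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos"], dtype=str)
    snp_ids = map_df["snp_id"].tolist()
    n_snps = len(snp_ids)

    ped_rows, allele_a, allele_b = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise IoError(
                    f"{prefix}.ped: row for {parts[1] if len(parts) > 1 else '?'} "
                    f"has {len(parts)} fields, expected {6 + 2 * n_snps}"
                )
            ped_rows.append(parts[:6])
            allele_a.append(parts[6::2])
            allele_b.append(parts[7::2])
    ped_df = pd.DataFrame(
        ped_rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "pheno"],
    )
    ped_df["sex"] = ped_df["sex"].map(_PED_TO_SEX)
    pedigree = Pedigree(ped_df.drop(columns="pheno"))

    a = np.asarray(allele_a, dtype="U8")
    b = np.asarray(allele_b, dtype="U8")
    snps = _snp_table(map_df, a, b, annotation, snp_ids)
    minor = snps["allele_minor"].to_numpy()[None, :]
    dosage = np.where(
        (a == "0") | (b == "0"),
        np.nan,
        (a == minor).astype(float) + (b == minor).astype(float),
    )
    order = np.array([snp_ids.index(s) for s in snps.index])
    return pedigree, GenotypeMatrix(
        ped_df["individual_id"].tolist(), snps, dosage[:, order]
    )


def _snp_table(map_df: pd.DataFrame, a: np.ndarray, b: np.ndarray,
               annotation: pd.DataFrame | None, snp_ids: list[str]) -> pd.DataFrame:
    chrom = map_df["chrom"].to_numpy()
    pos = map_df["pos"].astype(int).to_numpy()
    if annotation is not None:
        ann = annotation.set_index("snp_id") if "snp_id" in annotation.columns else annotation
        missing = [s for s in snp_ids if s not in ann.index]
        if missing:
            raise IoError(f"annotation lacks SNPs: {missing[:5]}")
        ann = ann.loc[snp_ids]
        snps = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "allele_minor": ann["allele_minor"].to_numpy(),
                "allele_major": ann["allele_major"].to_numpy(),
                "gene_label": ann.get("gene_label", pd.Series("unassigned",
                                                              index=ann.index)).to_numpy(),
            },
            index=pd.Index(snp_ids, name="snp_id"),
        )
    else:
        minor, major = [], []
        for j in range(len(snp_ids)):
            calls = np.concatenate([a[:, j], b[:, j]])
            calls = calls[calls != "0"]
            alleles, counts = np.unique(calls, return_counts=True)
            if len(alleles) == 1:
                alleles = np.append(alleles, "N")
                counts = np.append(counts, 0)
            order = np.lexsort((alleles, counts))  # count asc, then lexicographic
            minor.append(alleles[order[0]])
            major.append(alleles[order[-1]])
        snps = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "allele_minor": minor,
             "allele_major": major, "gene_label": "unassigned"},
            index=pd.Index(snp_ids, name="snp_id"),
        )
    return snps.sort_values(["chrom", "pos"])


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_annotation(path: str | os.PathLike, genotypes: GenotypeMatrix) -> None:
    out = genotypes.snps.reset_index()
    out = out.rename(columns={out.columns[0]: "snp_id"})
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str})


def read_dosage_tsv(path: str | os.PathLike,
                    annotation: pd.DataFrame) -> GenotypeMatrix:
    """Subjects x SNPs dosage TSV (header = snp ids, first column = subject)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA)
    ann = annotation.set_index("snp_id") if "snp_id" in annotation.columns else annotation
    snps = ann.loc[df.columns, ["chrom", "pos", "allele_minor", "allele_major"]].copy()
    snps["gene_label"] = ann.loc[df.columns].get("gene_label", "unassigned")
    snps = snps.sort_values(["chrom", "pos"])
    return GenotypeMatrix(df.index.astype(str).tolist(), snps,
                          df[snps.index].to_numpy(dtype=float))


def write_dosage_tsv(path: str | os.PathLike, genotypes: GenotypeMatrix) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", na_rep=NA)


def write_metabolites(path: str | os.PathLike, classes_path: str | os.PathLike,
                      panel: MetabolitePanel) -> None:
    panel.values.to_csv(path, sep="\t", na_rep=NA)
    panel.classes.rename("class").rename_axis("metabolite_id").to_csv(
        classes_path, sep="\t"
    )


def read_metabolites(path: str | os.PathLike,
                     classes_path: str | os.PathLike) -> MetabolitePanel:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=NA)
    classes = pd.read_csv(classes_path, sep="\t", index_col=0)["class"]
    return MetabolitePanel(values, classes)


def write_covariates(path: str | os.PathLike, covariates: pd.DataFrame) -> None:
    covariates.to_csv(path, sep="\t", na_rep=NA)


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA)
    df.index = df.index.astype(str)
    return df


def write_effect_plan(path: str | os.PathLike, plan: EffectPlan) -> None:
    plan.entries.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_effect_plan(path: str | os.PathLike) -> EffectPlan:
    return EffectPlan(pd.read_csv(path, sep="\t", dtype={"snp_id": str,
                                                         "metabolite_id": str,
                                                         "stratum": str}))
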