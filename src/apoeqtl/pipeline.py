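"""End-to-end orchestration: simulate -> qc -> associate -> contrast ->
diagnose -> enrich, as one reproducible run.

A run is driven by a flat sectioned configuration (one section per stage;
unknown sections or keys are rejected before anything executes), writes
every stage's tables as TSV under the output directory, and records a
manifest with the seed, thresholds, per-file checksums, stage timings and
package versions.  Re-running with the same configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import EffectPlan, MetabolitePanel
from . import io as _io
from . import syndata, gqc, assoc, hetero, diagnostics, enrich as _enrich

__all__ = ["run_all", "report", "RunManifest", "PipelineConfigError"]


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


_SCHEMA: dict[str, set[str]] = {
    "simulate": {
        "n_families", "family_size_dist", "n_snps", "ld_block_size",
        "maf_range", "ld_mutation_rate", "recomb_rate", "apoe_hap_freqs",
        "sigma_g2", "sigma_e2", "n_lipid", "n_polar", "covariate_params",
        "binary_params", "covariate_effects", "apoe_ldlc_shift", "seed",
        "effects",
    },
    "input": {"dir"},
    "qc": {"maf", "hwe", "miss", "mendel", "hwe_founders_only"},
    "associate": {"pcs", "fdr", "fdr_family", "min_stratum_size", "metabolites"},
    "contrast": {"alpha", "m", "interactions", "sex_contrast"},
    "pooled": {"enabled"},
    "diagnose": {"enabled", "ld_snps"},
    "enrich": {"gmt", "background", "by_class"},
}


def validate_config(config: dict) -> None:
    unknown_sections = set(config) - set(_SCHEMA)
    if unknown_sections:
        raise PipelineConfigError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, keys in config.items():
        if not isinstance(keys, dict):
            raise PipelineConfigError(f"section {section!r} must be a mapping")
        unknown = set(keys) - _SCHEMA[section]
        if unknown:
            raise PipelineConfigError(
                f"unknown keys in section {section!r}: {sorted(unknown)}"
            )
    if "simulate" in config and "input" in config:
        raise PipelineConfigError("give either 'simulate' or 'input', not both")
    if "simulate" not in config and "input" not in config:
        raise PipelineConfigError("config needs a 'simulate' or 'input' section")


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    stages: dict = field(default_factory=dict)   # name -> {status, seconds}
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    thresholds: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @property
    def completed(self) -> bool:
        return all(s.get("status") == "ok" for s in self.stages.values())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(manifest: RunManifest, outdir: Path, name: str, df: pd.DataFrame,
           index: bool = False) -> None:
    path = outdir / f"{name}.tsv"
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
    manifest.outputs[name] = {"path": str(path), "sha256": _sha256(path)}


def run_all(config: dict, outdir: str | Path) -> RunManifest:
    """Execute the full pipeline; halts on stage failure with a partial
    manifest (written as ``manifest.json`` either way)."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("simulate", {}).get("seed")
    manifest = RunManifest(config=config, seed=seed,
                           versions={"apoeqtl": __version__,
                                     "numpy": np.__version__,
                                     "pandas": pd.__version__})
    state: dict = {}
    stages = [
        ("load", _stage_load),
        ("qc", _stage_qc),
        ("associate", _stage_associate),
        ("contrast", _stage_contrast),
        ("pooled", _stage_pooled),
        ("diagnose", _stage_diagnose),
        ("enrich", _stage_enrich),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            try:
                fn(config, state, manifest, outdir)
            except Exception as exc:
                manifest.stages[name] = {
                    "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest.stages[name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 3),
            }
    finally:
        manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_load(config, state, manifest, outdir):
    if "simulate" in config:
        params = dict(config["simulate"])
        effects = params.pop("effects", [])
        for key in ("maf_range", "apoe_hap_freqs"):
            if key in params:
                params[key] = tuple(params[key])
        sim_cfg = syndata.SimConfig(**params)
        plan = EffectPlan(pd.DataFrame(effects)) if effects else EffectPlan()
        cohort = syndata.simulate_cohort(sim_cfg, plan)
        syndata.write_fixture(outdir / "fixture", cohort)
        state.update(pedigree=cohort.pedigree, genotypes=cohort.genotypes,
                     covariates=cohort.covariates, panel=cohort.metabolites,
                     plan=plan)
    else:
        d = Path(config["input"]["dir"])
        for stem in ("cohort.ped", "cohort.map", "annotation.tsv",
                     "covariates.tsv", "metabolites.tsv",
                     "metabolite_classes.tsv"):
            if not (d / stem).exists():
                raise PipelineConfigError(f"missing input file: {d / stem}")
        ann = _io.read_annotation(d / "annotation.tsv")
        ped, geno = _io.read_ped_map(d / "cohort", annotation=ann)
        state.update(
            pedigree=ped, genotypes=geno,
            covariates=_io.read_covariates(d / "covariates.tsv"),
            panel=_io.read_metabolites(d / "metabolites.tsv",
                                       d / "metabolite_classes.tsv"),
            plan=None,
        )


def _stage_qc(config, state, manifest, outdir):
    qc_cfg = config.get("qc", {})
    t = gqc.QcThresholds(
        maf_min=qc_cfg.get("maf", 0.01),
        hwe_p_min=qc_cfg.get("hwe", 1e-6),
        missing_max=qc_cfg.get("miss", 0.05),
        mendel_max=qc_cfg.get("mendel", 0.02),
        hwe_founders_only=qc_cfg.get("hwe_founders_only", True),
    )
    manifest.thresholds.update(maf=t.maf_min, hwe=t.hwe_p_min,
                               missing=t.missing_max, mendel=t.mendel_max)
    filtered, qc_report = gqc.apply_qc(state["genotypes"], state["pedigree"], t)
    g429358, g7412 = gqc.apoe_genotype_strings(state["genotypes"])
    strata = gqc.assign_apoe_groups(g429358, g7412)
    aligned, flip_log = gqc.align_effect_alleles(filtered, strata)
    state.update(genotypes=aligned, strata=strata)
    _write(manifest, outdir, "qc_report", qc_report)
    _write(manifest, outdir, "allele_flips", flip_log)
    counts = strata.counts().rename("n").rename_axis("stratum").reset_index()
    _write(manifest, outdir, "strata_counts", counts)


def _stage_associate(config, state, manifest, outdir):
    a = config.get("associate", {})
    fdr = a.get("fdr", 0.05)
    manifest.thresholds["fdr"] = fdr
    panel = state["panel"]
    if a.get("metabolites"):
        keep = list(a["metabolites"])
        panel = MetabolitePanel(panel.values[keep], panel.classes[keep])
    kinship = assoc.pedigree_kinship(state["pedigree"])
    pcs = assoc.genotype_pcs(state["genotypes"], state["pedigree"],
                             k=a.get("pcs", 5))
    results, discoveries = assoc.run_stratified_scan(
        state["genotypes"], panel, state["covariates"], kinship,
        state["strata"], pcs=pcs, fdr=fdr,
        fdr_family=a.get("fdr_family", "stratum"),
        min_stratum_size=a.get("min_stratum_size", 50),
    )
    state.update(kinship=kinship, pcs=pcs, panel_used=panel,
                 results=results, discoveries=discoveries)
    _write(manifest, outdir, "associations", results)
    _write(manifest, outdir, "discoveries", discoveries)


def _stage_contrast(config, state, manifest, outdir):
    c = config.get("contrast", {})
    alpha = c.get("alpha", 0.05)
    manifest.thresholds["bonferroni_alpha"] = alpha
    contrasts = hetero.find_group_specific(state["discoveries"], state["results"],
                                           alpha=alpha, m=c.get("m"))
    manifest.thresholds["bonferroni_m"] = contrasts.attrs.get("bonferroni_m", 0)
    state["contrasts"] = contrasts
    _write(manifest, outdir, "contrasts", contrasts)
    sig = contrasts[contrasts.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    if c.get("interactions", True) and len(sig):
        rows = []
        for _, r in sig.iterrows():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(hetero.interaction_test(
                    state["genotypes"], state["panel_used"], state["covariates"],
                    state["kinship"], state["strata"], r.snp_id, r.metabolite_id,
                    pair=(r.group_a, r.group_b), pcs=state["pcs"],
                ))
        _write(manifest, outdir, "interactions", pd.DataFrame(rows))
    else:
        _write(manifest, outdir, "interactions", pd.DataFrame(
            columns=["snp_id", "metabolite_id", "pair", "beta_int", "se_int",
                     "p_int", "n_used", "converged"]))
    if c.get("sex_contrast", True) and len(sig):
        entries = (state["discoveries"]
                   .merge(sig[["snp_id", "metabolite_id"]].drop_duplicates(),
                          on=["snp_id", "metabolite_id"]))
        sex = hetero.sex_contrast(state["genotypes"], state["panel_used"],
                                  state["covariates"], state["kinship"],
                                  state["strata"], entries, pcs=state["pcs"])
        _write(manifest, outdir, "sex_contrasts", sex)


def _stage_pooled(config, state, manifest, outdir):
    if not config.get("pooled", {}).get("enabled", True):
        return
    pooled_results, overlap = hetero.pooled_scan(
        state["genotypes"], state["panel_used"], state["covariates"],
        state["kinship"], state["strata"], state["discoveries"],
        pcs=state["pcs"], fdr=manifest.thresholds.get("fdr", 0.05),
        group_specific=state.get("contrasts"),
    )
    state["pooled_overlap"] = overlap
    _write(manifest, outdir, "pooled_associations", pooled_results)
    _write(manifest, outdir, "pooled_overlap", overlap)


def _stage_diagnose(config, state, manifest, outdir):
    d = config.get("diagnose", {})
    if not d.get("enabled", True):
        return
    g = state["genotypes"]
    ld_snps = d.get("ld_snps")
    g_ld = g.subset_snps(ld_snps) if ld_snps else g
    ld = diagnostics.ld_matrix(g_ld, ped=state["pedigree"])
    _write(manifest, outdir, "ld_matrix", ld, index=True)
    v = diagnostics.vif(g, state["covariates"])
    _write(manifest, outdir, "vif", v)
    summaries, overlaps = diagnostics.metabolite_summaries(
        state["panel_used"], state["strata"])
    _write(manifest, outdir, "metabolite_summaries", summaries)
    _write(manifest, outdir, "metabolite_ci_overlap", overlaps)
    tables = diagnostics.gene_group_clustering(state["discoveries"])
    incidence = pd.concat(
        {k: t for k, t in tables.items()}, names=["set", "gene"]
    ).reset_index()
    _write(manifest, outdir, "gene_clustering", incidence)


def _stage_enrich(config, state, manifest, outdir):
    e = config.get("enrich", {})
    if not e.get("gmt"):
        return
    library = _enrich.load_gmt(e["gmt"], background_size=e.get("background"))
    disc = state["discoveries"]
    frames = []
    for stratum, grp in disc.groupby("stratum"):
        hits = sorted(set(grp["metabolite_id"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = _enrich.enrich_table(hits, library)
        table.insert(0, "stratum", stratum)
        frames.append(table)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["stratum", "pathway", "total", "hits",
                                      "p", "q"]))
    _write(manifest, outdir, "enrichment", out)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(manifest: RunManifest) -> str:
    """Human-readable run summary: per-stratum discovery counts,
    group-specific contrasts and pooled replications."""
    outdir = {k: Path(v["path"]) for k, v in manifest.outputs.items()}
    lines = ["apoeqtl run summary", "=" * 40]
    ran = {k for k, v in manifest.stages.items() if v.get("status") == "ok"}
    if "associate" in ran and "discoveries" in outdir:
        disc = pd.read_csv(outdir["discoveries"], sep="\t")
        counts = disc.groupby("stratum").size() if len(disc) else pd.Series(dtype=int)
        for s in ("E2", "E3", "E4"):
            lines.append(f"discoveries in {s}: {int(counts.get(s, 0))}")
        lines.append(f"total discoveries: {len(disc)}")
    else:
        lines.append("associate: not run")
    if "contrast" in ran and "contrasts" in outdir:
        con = pd.read_csv(outdir["contrasts"], sep="\t")
        n_sig = int(con["significant"].fillna(False).sum()) if len(con) else 0
        pairs = (con[con["significant"] == True]  # noqa: E712
                 [["snp_id", "metabolite_id"]].drop_duplicates())
        lines.append(f"group-specific contrasts (pair-level): {n_sig}")
        lines.append(f"group-specific (snp, metabolite) pairs: {len(pairs)}")
    else:
        lines.append("contrast: not run")
    if "pooled" in ran and "pooled_overlap" in outdir:
        ov = pd.read_csv(outdir["pooled_overlap"], sep="\t")
        n_rep = int(ov["replicates_pooled"].fillna(False).sum()) if len(ov) else 0
        lines.append(f"discoveries replicating in pooled sample: {n_rep}")
    else:
        lines.append("pooled: not run")
    for name, _ in (("diagnose", 0), ("enrich", 0)):
        if name not in ran:
            lines.append(f"{name}: not run")
    lines.append("=" * 40)
    return "\n".join(lines)
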