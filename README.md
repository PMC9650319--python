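# apoeqtl

APOE-allele-stratified SNP–metabolite association analysis with
family-based linear mixed models.

## The problem

The APOE ε2/ε3/ε4 polymorphism — defined jointly by rs429358 and rs7412 —
modulates lipid metabolism and the risk of Alzheimer's disease and
coronary artery disease. Association signals between SNPs in the ~1 Mb
APOE gene cluster on chromosome 19q13.3 and plasma metabolite
concentrations can therefore differ between carriers of different APOE
alleles, and an analysis pooled over all subjects can miss effects that
are specific to one allele group or even point in opposite directions in
two groups.

`apoeqtl` implements the two-stage stratified analysis for this setting,
for cohorts with a family design (parents and offspring), together with a
synthetic family-cohort generator for method validation when the real
(access-restricted) cohort data are unavailable. It is aimed at
statistical geneticists and biostatisticians working with
metabolomics-by-genotype data in family studies.

**Stage one** fits, separately in each APOE stratum — E2 (ε2ε2/ε2ε3), E3
(ε3ε3), E4 (ε3ε4/ε4ε4), with ε2ε4 carriers excluded — an additive
kinship linear mixed model for every (SNP, metabolite) pair:

```
log y = Xβ + g·b + u + e,    u ~ N(0, σg² K),    e ~ N(0, σe² I)
```

where `log y` is the log metabolite concentration, `X` holds the clinical
covariates plus the top five genetic principal components, `g` is the
minor-allele dosage, and `K = 2Φ` is the expected relationship matrix
from the pedigree. Variance components are estimated once per
(metabolite, stratum) by REML under the null, then fixed for the SNP
scan. Discoveries are declared at Benjamini–Hochberg FDR < 0.05 within
each stratum.

**Stage two** contrasts each discovery's effect between stratum pairs
with the 1-df heterogeneity statistic

```
χ² = (b₁ − b₂)² / (SE₁² + SE₂²)
```

judged at a Bonferroni threshold α/m with m the total number of stage-one
discoveries (0.05/70 = 7.14E−04 for a 70-association family).
Group-specific findings are corroborated by SNP×group interaction models
on the pooled stratum pair, checked for sex heterogeneity, and compared
with a re-analysis in the pooled sample, where opposite-sign effects
cancel.

Supporting modules provide genotype QC (MAF ≥ 1%, exact Hardy–Weinberg
p ≥ 1e−6, missingness ≤ 5%, Mendel error rates ≤ 2%), LD matrices (r² /
D′ from phase or two-locus EM), SNP–covariate multicollinearity (VIF),
per-stratum metabolite distribution summaries, gene-by-stratum clustering
tables, and hypergeometric pathway over-representation against a GMT
library.

## Worked example

Simulate a cohort of 452 nuclear families (~1,800 subjects, matching the
emulated study's size and covariate distributions), plant an E2-specific
effect of +0.8 log units per minor allele on one polar analyte
(β_E3 = −0.1), and run the whole pipeline:

```python
from apoeqtl import pipeline

config = {
    "simulate": {
        "n_families": 452, "n_snps": 94, "n_lipid": 2, "n_polar": 2,
        "seed": 1,
        "effects": [
            {"snp_id": "snp001", "metabolite_id": "polar_001",
             "stratum": "E2", "beta_true": 0.8},
            {"snp_id": "snp001", "metabolite_id": "polar_001",
             "stratum": "E3", "beta_true": -0.1},
        ],
    },
    "associate": {"pcs": 5},
}
manifest = pipeline.run_all(config, "demo_run")
print(pipeline.report(manifest))
```

```
apoeqtl run summary
========================================
discoveries in E2: 2
discoveries in E3: 0
discoveries in E4: 0
total discoveries: 2
group-specific contrasts (pair-level): 3
group-specific (snp, metabolite) pairs: 2
discoveries replicating in pooled sample: 0
========================================
```

The discoveries table (`demo_run/discoveries.tsv`) recovers the planted
effect — β̂ = 0.819 ± 0.124 for the planted SNP, within one standard
error of the true 0.8 — plus a shadow discovery at snp006, which sits in
the same LD block:

```
stratum snp_id metabolite_id     beta       se            p            q
     E2 snp001     polar_001 0.818934 0.124340 4.510775e-11 1.714095e-08
     E2 snp006     polar_001 0.511972 0.135996 1.668032e-04 3.169261e-02
```

Stage two flags both as E2-specific with opposite effect directions in E2
and E3 (`demo_run/contrasts.tsv`):

```
snp_id metabolite_id       b1      se1        b2      se2      chi2            p  significant  opposite_direction
snp001     polar_001 0.818934 0.124340 -0.062831 0.055443 41.949658 9.365375e-11         True                True
snp006     polar_001 0.511972 0.135996 -0.061333 0.061939 14.718323 1.248273e-04         True                True
```

Neither replicates in the pooled sample (the +0.8 effect in the ~14% E2
subgroup is diluted by the null E3/E4 majority) — the pattern the
stratified design exists to catch.

The modelling objects can also be used directly. Fitting the null mixed
model for one analyte on the whole cohort (true variance components
σg² = σe² = 0.5):

```python
from apoeqtl import assoc
from apoeqtl.lmm import KinshipLMM

K = assoc.pedigree_kinship(cohort.pedigree)
logp = assoc.log_transform(cohort.metabolites)
data = cohort.covariates[["sex", "bmi", "tc", "tg"]].join(
    logp.values[["polar_002"]]).dropna()
result = KinshipLMM.from_dataframe(
    data, "polar_002", ["sex", "bmi", "tc", "tg"], K).fit()
print(result.summary())
```

```
Kinship linear mixed model (REML)
==========================================================
No. observations:     1814   converged: True
sigma_g^2:     0.4628   sigma_e^2:     0.4947
heritability ratio h:  0.4833   REML loglik: -829.976
----------------------------------------------------------
                      coef   std err        z      P>|z|
const              -0.3616    0.1956   -1.849  6.447e-02
sex                 0.0240    0.0443    0.541  5.883e-01
bmi                 0.0144    0.0050    2.901  3.717e-03
tc                 -0.0004    0.0007   -0.609  5.426e-01
tg                  0.0007    0.0003    2.555  1.063e-02
==========================================================
```

`result.scan(dosages)` then tests SNPs one at a time against this null
fit. A `click` CLI wraps the same stages
(`apoeqtl simulate | qc | associate | contrast | enrich | run-all`).

## Documentation

See `docs/methods.md` for the model, the synthetic-data design, numerical
choices and known limitations.
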