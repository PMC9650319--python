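# Methods

This note documents the statistical model, the synthetic-data design, the
numerical choices and the limitations of `apoeqtl`.

## Stage-one model

For one metabolite and one APOE stratum the analysis model is

    log y_i = x_i' β + g_i b + u_i + e_i,
    u ~ N(0, σg² K),   e ~ N(0, σe² I),

with `y_i` the (strictly positive) metabolite concentration of subject
`i`, `x_i` the fixed-effect covariates — sex, birth year, smoking,
Alzheimer's status, BMI, blood pressures, fasting glucose, lipid panel
(TC, LDL-C, HDL-C, TG) and eGFR, plus the top five genetic principal
components — `g_i` the minor-allele dosage, and `K` the expected
relationship matrix (2 × the pedigree kinship coefficient; parent–
offspring and full-sib entries 0.5, non-inbred diagonal 1). The natural
log is used; the base only rescales `b`, not the test statistics.

### REML fitting

`KinshipLMM.fit()` eigendecomposes `K = U D U'` once and rotates the
model so observations are independent with variances
`σ² (h d_i + 1 − h)`, where `h = σg² / (σg² + σe²)` and
`σ² = σg² + σe²`. The scale `σ²` profiles out in closed form, leaving a
one-dimensional restricted-likelihood maximization in `h` on [0, 1),
solved by a 40-point grid followed by bounded scalar refinement
(`xatol = 1e−8`). Boundary estimates (`h = 0`, no family variance) are
legitimate results, not errors. With `K = I` the likelihood is flat in
`h` and the fitted total variance equals the OLS residual variance.

### SNP scan

SNPs are tested one at a time by generalized least squares with `h` held
at its null-model estimate (the one-null-fit-per-trait convention of
mixed-model association software; 94 SNPs make per-SNP REML affordable
too, but fixing `h` keeps the scan exactly linear). The residual scale is
re-profiled per SNP with the SNP in the model, so the scan reduces
*exactly* to ordinary least squares when `K = I` — a property the test
suite checks to 1e−8 against an independent OLS fit. Wald p-values use
the asymptotic normal reference. Missing dosages are mean-imputed per
SNP within the analyzed subset; SNPs monomorphic in a stratum, or
collinear with the covariates, yield flagged missing results.

### Multiplicity

Benjamini–Hochberg q-values are computed by the step-up rule
`q(i) = min_{j: rank ≥ rank(i)} p(j)·m/rank(j)`, capped at 1. The default
FDR family is all tests within one stratum (94 SNPs × all metabolites);
per-metabolite families are available via `fdr_family="metabolite"`. The
family choice was genuinely open; the per-stratum-global family is the
more conservative reading and is the default.

### Genetic principal components

PC loadings are computed on founders only (offspring duplicate their
parents' genotypes and would otherwise dominate the leading axes) and all
subjects are projected onto the founder loadings. Dosages are centered
and variance-standardized with founder statistics. Signs are fixed by
making each loading's largest-magnitude entry positive, so results are
deterministic. PCs are computed once on the pooled cohort and reused in
every stratum.

## Stage two

For every stage-one discovery the effect is contrasted between the three
stratum pairs (E2 vs E3, E4 vs E3, E2 vs E4) with
`χ² = (b₁ − b₂)²/(SE₁² + SE₂²)` on 1 df. The Bonferroni denominator is
the total number of stage-one discoveries across strata (not the number
of SNPs): this is the convention that yields the reference threshold
0.05/70 = 7.14E−04 for a 70-association family, and both readings of
"number of tests" can be obtained by passing `m` explicitly.

Interaction corroboration fits the mixed model on the pooled pair of
contrasted strata with fixed effects covariates + group indicator +
dosage + dosage×group, and Wald-tests the interaction coefficient; the
kinship matrix is subset to the pooled pair. A binary (two-stratum)
pooling is used rather than a three-level model so that each pairwise
contrast gets exactly one interaction p-value. The sex contrast refits
the stage-one scan within males and within females of the discovery's
stratum (dropping sex from the design) and applies the same χ² at
nominal 0.05. The pooled re-analysis runs stage one on E2 ∪ E3 ∪ E4
(ε2ε4 carriers stay excluded) with BH over the pooled family.

## Genotype QC

Filters run in a fixed order — subject missingness, SNP missingness,
MAF, HWE, Mendel (SNP), Mendel (subject), Mendel (family) — each
recomputed on the survivors of the previous step, with defaults
MAF ≥ 0.01, HWE p ≥ 1e−6, missingness ≤ 0.05, Mendel ≤ 0.02. Putting
missingness first keeps the MAF/HWE denominators stable; the cascade is
idempotent (a second pass removes nothing).

The HWE test is the exact conditional test with probability-mass
ordering (no mid-p): given the allele counts, the p-value sums the
probabilities of all heterozygote counts whose conditional probability
does not exceed the observed one. It is evaluated on founders only, since
relatedness distorts genotype proportions. Mendel errors count both duos
and trios; the informative-test denominator is the number of
(offspring-with-genotyped-parent, SNP) combinations with the relevant
calls present, and an error is attributed to the offspring, its family
and the SNP.

APOE strata follow the rs429358/rs7412 haplotype logic: ε2 = (T, T),
ε3 = (T, C), ε4 = (C, C). The double heterozygote (TC, TC-at-rs7412)
phases as either ε2ε4 or ε3 + the essentially non-existent (C, T)
haplotype; it is resolved as ε2ε4 and excluded. Genotype pairs requiring
a (C, T) haplotype outright are excluded as implausible. Effect alleles
are aligned to the pooled-sample minor allele before any scan so that
`b₁` and `b₂` in a contrast count the same allele; exact 50/50
frequencies break ties to the lexicographically smaller allele, and all
flips are logged.

## Synthetic cohort

The generator produces the structure the analysis assumes, with defaults
set to the emulated study's conditions:

- **Pedigrees.** 452 nuclear families; offspring per family
  ~ min(1 + Poisson(1), 4), giving ≈ 1,800 subjects. Founders are one
  male/one female; offspring sex is Bernoulli(0.53 female).
- **Regional SNPs.** 94 SNPs spaced 10 kb across a ~1 Mb region, MAF
  targets uniform on [0.05, 0.45], organized in contiguous LD blocks of 6.
  Within a block each haplotype thresholds one shared latent uniform at
  every SNP's MAF; with probability 0.15 a site redraws its own uniform.
  This gives exact Bernoulli(MAF) marginals, positive within-block r² and
  independent blocks. SNPs map onto 26 gene labels of the APOE cluster.
- **Gene dropping.** Founders take two pool haplotypes; each offspring
  receives one randomly chosen haplotype per parent. No recombination
  within the region by default (it is ~1 Mb; a per-meiosis crossover
  probability is configurable for stress tests). Mendel errors are zero
  by construction, which the QC module verifies.
- **APOE SNPs.** Founder haplotypes ε2/ε3/ε4 drawn at (0.08, 0.80, 0.12)
  and gene-dropped. These frequencies were chosen so the post-exclusion
  group shares land at E2 ≈ 13.7%, E3 ≈ 65.3%, E4 ≈ 21.0% — the shares
  implied by the emulated cohort's group counts — with ε2ε4 carriers
  (expected 2·0.08·0.12 ≈ 1.9% of founder genotype mass) excluded.
- **Covariates.** Continuous covariates are normal at the emulated
  cohort's mean (SD) — e.g. TC 203.81 (32.63) mg/dl — except TG, which is
  log-normal with matched moments to keep it positive; binaries are
  Bernoulli. Covariates are independent of genotype by default so null
  calibration is clean; an optional APOE→LDL-C shift hook exists for
  confounding experiments but is off by default.
- **Metabolites.** 217 analytes (140 labeled lipid, 77 polar; the split
  is a labeling convention only — it affects reporting and enrichment
  grouping, nothing in the model). Log concentration = small effects of
  standardized covariates + planted per-stratum SNP effects + a family
  polygenic effect drawn per family from N(0, σg²·2Φ) + N(0, σe²)
  residual, exponentiated. Defaults σg² = σe² = 0.5 give full-sib
  log-concentration correlation 0.25. Planted effect sizes in the test
  and acceptance experiments (β ≈ 0.8 vs −0.1, SE ≈ 0.15–0.2 in the
  smallest stratum) sit at the scale of the largest reference
  group-specific association.

Everything is deterministic given the seed: each operation derives an
independent stream from (seed, fixed salt), so fixtures are byte-identical
across runs.

What the generator does **not** emulate: LC/MS measurement artifacts,
realistic metabolite–metabolite correlation networks, population
stratification within the cohort, genotype–covariate confounding (unless
the hook is enabled), X-chromosome inheritance. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data features.

## Diagnostics

LD is computed on founders only (relatedness inflates LD), from true
phase when available, else by two-locus EM on unphased genotypes (50
iterations or Δ < 1e−10; only the double heterozygote is
phase-ambiguous). Matrices are written with r² in the lower-left and D′
in the upper-right triangle. Near D = 0, D′ is ill-conditioned, so the
EM-vs-phase convergence checks target r². VIF per SNP is 1/(1 − R²) from
regressing dosage on the full covariate set. Distribution summaries give
per-(analyte, stratum) means with normal-approximation 95% CIs, a
mean-different-from-zero test, and pairwise CI-overlap flags (overlap =
non-empty interval intersection).

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) for a
pathway of size K containing k of n input metabolites against a
background of size N, with BH over tested pathways. The background is an
explicit parameter (default: the union of library members) because
enrichment p-values are meaningful only conditional on it; hosted
enrichment services use proprietary backgrounds that cannot be
reconstructed, so their printed p-values are reproducible only given the
same N. Name matching is exact after case/whitespace normalization — no
fuzzy chemical-identifier resolution.

## Problem sizes used in validation

The test-suite and acceptance experiments run at sizes chosen to exercise
the full design while staying desk-scale: calibration of the scan's
type-I error uses 10,000 null tests (500 analytes × 20 SNPs, 100
families); contrast type-I error uses 10,000 simulated estimate pairs;
end-to-end recovery uses twenty ~1,800-subject cohorts with the full
94-SNP panel; REML recovery uses twenty 500-sib-pair replicates. The
SNP-panel size matters beyond runtime: with very small panels the five
genetic PCs absorb a material share of any single SNP's dosage variance
and attenuate its estimated effect, so power experiments are run at the
full 94-SNP panel.

## Known limitations

- The Wald tests are asymptotic; in very small strata (tens of subjects)
  exact small-sample references would be preferable.
- The empirical-GRM path mean-imputes missing dosages; with high
  missingness a proper dosage model would be better.
- The EM LD estimator assumes Hardy–Weinberg within the founder sample.
- One variance-component pair per (metabolite, stratum) is assumed; no
  per-SNP re-estimation by default (available at higher cost).
- The pipeline is single-threaded by design; the full 94 × 217 × 3 scan
  takes a few minutes on one CPU.
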