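# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design being modelled

The pipeline implements a two-cohort germline predisposition screen: rare
deleterious variants are called in a discovery cohort, validated in an
independent cohort processed by the same pipeline, and tested per variant
for over-representation against a large population reference that publishes
allele counts (AC out of AN alleles) rather than genotypes. Candidate novel
predisposition genes are non-DDR genes with at least one significantly
enriched variant that are not already on a user-supplied list of previously
reported genes.

## QC filtering

Five per-variant criteria, applied in a fixed order for reporting (the
retained set is order-independent because each criterion is per-variant):

| criterion | default | comparison |
|---|---|---|
| population MAF | 0.01 | strict `<`, max over available EAS sources, absent source = 0 |
| exonic | required | boolean |
| total depth | 20 reads | strict `>` |
| strand bias (Phred FS) | 60 | keep `<= 60` (default mode) |
| carrier VAF | 0.25 | `>=`, max over carriers |

Two deliberate knobs:

* **Strand bias.** The conventional reading of a Phred-scaled Fisher strand
  score is that *large* values indicate bias, so the default mode retains
  FS ≤ 60. A literal mode (`retain_gt_literal`) keeping FS > 60 exists for
  comparison with sources that state the rule the other way; under the
  literal mode only strand-biased calls survive, which we consider a
  transcription artifact rather than an intended filter.
* **MAF combination.** "Rare in any East Asian database" is ambiguous; the
  default requires rarity in *every* available source (max < 0.01), with a
  `min` mode requiring rarity in at least one.

Records missing a field a stage needs (no depth, no strand score, no usable
VAF) are dropped at that stage and counted in the funnel report rather than
raising, since real annotation tables are routinely incomplete.

Panel intersection is exact, case-sensitive symbol matching after whitespace
stripping; matched variants inherit the panel's pathway label and DDR flag.
Coordinates are 1-based VCF-style and variants match the reference table
only on exact (chrom, pos, ref, alt); inputs must be left-aligned and
parsimonious, and a validation pass rejects non-parsimonious allele pairs
rather than guessing a normalization.

## ACMG classification

`combine_evidence` implements the published rule table (Pathogenic,
Likely pathogenic, Benign, Likely benign combinations over PVS1, PS1–4,
PM1–6, PP1–5, BA1, BS1–4, BP1–7), with each code counted at most once.
Two conventions were open and are fixed as follows:

* **Contradiction.** If a benign-direction classification fires while any
  pathogenic-direction code is present — or a pathogenic-direction
  classification fires while any benign-direction code is present — the
  result is VUS. This is the conservative reading of the guideline's
  "contradictory criteria" clause; e.g. {PVS1, BA1} → VUS even though PVS1
  alone fires no pathogenic combination.
* **Likely benign** fires on (≥1 BS and ≥1 BP) or ≥2 BP.

The combiner is verified against a literally transcribed clause-by-clause
oracle on 10^5 random evidence subsets, and satisfies directional
monotonicity (adding pathogenic evidence never moves the tier toward
benign, and vice versa).

The default evidence assigner is deliberately minimal — PVS1 for null
variants (stop-gain, frameshift, splicing) in genes flagged as acting
through loss of function, PM2 below 10⁻⁴ in both the reference and every
EAS source, BA1 above 5% in any source, PP3/BP4 passed through from the
annotation table — and is pluggable, because published cohort
classifications cannot be reproduced without the original per-variant
evidence assignments. The synthetic annotation tables therefore carry
evidence codes directly, so the classifier path is tested independently of
the assigner.

## Enrichment statistics

Default 2×2 construction is allele counts: a = cohort alternate alleles,
b = 2·n − a, c = reference AC, d = AN − AC (reference tables publish
alleles, not carriers); a carrier-mode alternative treats AC as a carrier
estimate out of AN/2 individuals. Variants absent from the reference
resolve to AC = 0 with AN = 18,394 (2 × 9,197 individuals), since
population databases omit unobserved variants.

* p-values: two-sided Fisher exact (sum of same-margin tables no more
  probable than the observed one), computed on the raw integer table and
  verified against exact-rational exhaustive enumeration on all 246,015
  tables with both margins ≤ 30 (relative error < 10⁻⁷).
* Multiplicity: Benjamini–Hochberg step-up across the variants of one run;
  Bonferroni is available as an option where a stricter family-wise
  control is preferred. FDR is the default because the gene-level calls
  are defined by FDR ≤ 0.05.
* Odds ratios: OR = (a/b)/(c/d) with Woolf logit CI
  exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)); when any cell is zero, 0.5 is
  added to **all four** cells (Haldane–Anscombe) for the OR and CI only.
* Direction: a significant variant must also have case frequency above
  reference frequency, so reported significant ORs are ≥ 1.
* VUS-level screens reuse the same machinery with a raw p ≤ 0.05 cutoff
  and no FDR (`use_raw_p=True`), matching the convention for
  uncertain-significance scans.

## Cohort summaries and clinical association

Percentages are rounded half-up to one decimal (33.3%, 30.6%, 25.1%-style
reporting). Pathway burden counts each gene in exactly one pathway;
patient-level fractions use the union of carriers per pathway, so a patient
carrying variants in two pathways counts once in each. Dichotomous traits
(metastasis, castration resistance within one year) use Fisher exact with a
continuity-corrected OR; continuous/ordinal traits (age, PSA, ISUP) use the
Wilcoxon rank-sum test — exact when the combined sample is ≤ 12 without
ties, otherwise the normal approximation with tie correction and no
continuity correction. A 1,000-replicate null simulation puts both tests'
type-I error at α = 0.05 within ±0.02 (the Fisher rate sits slightly below
0.05 because of the discreteness of exact tests on 2×2 margins).

## Logistic model and AUC

The metastasis model uses log10(PSA+1) (PSA spans three orders of
magnitude), ISUP grade as an ordinal integer 1–5, and binary any-VUS
carrier indicators for six PI3K-Akt genes — binary mutation status is the
only germline datum available, so it is the default encoding. Fitting is
maximum likelihood via IRLS: convergence when max|Δβ| < 10⁻⁸ (≤ 100
iterations); if coefficients diverge past |β| > 15 (the signature of
separation) the model is refit with a small ridge penalty (λ = 10⁻⁴,
intercept unpenalized) and flagged. The implementation agrees with an
independent ML fit to 10⁻⁶ on shared data. AUC is the Mann–Whitney rank
form of (concordant + ½·ties)/(n₊·n₋); ROC points for plotting come from
scikit-learn.

## Synthetic-data model

The generator's defaults are the emulated study conditions:

* **Cohorts:** 100 (discovery) and 167 (validation) patients.
* **Planted deleterious variants:** 36 variants in 25 genes; pathway
  spectrum 12/7/6/4/4/1/1/1 (DNA methylation, DDR, tyrosine-protein
  kinase, GPCR signaling, peroxisome, MAPK/ERK, ErbB, cell cycle) and
  consequence spectrum 12 nonsynonymous / 11 stop-gain / 7 frameshift
  deletion / 6 frameshift insertion. Carrier draws are independent
  Bernoulli per patient: 34 variants at probability 0.008 (singletons in
  expectation), one recurrent frameshift at 0.04 and one recurrent
  stop-gain at 0.02, for an aggregate carrier prevalence of ~0.29.
  Fifteen variants are essentially absent from the reference (enriched
  truth); the remainder are frequency-matched nulls.
* **Background:** 40 rare benign/VUS variants per patient (≈ 4,200
  in-panel variants per 100-patient cohort), population frequency
  ~ Beta(0.5, 2000) truncated below 0.01, 59% VUS / 41% benign, one
  random carrier each; 5% receive a deliberately failing QC field to
  exercise the funnel.
* **Reference:** 9,197 diploid individuals (AN = 18,394 everywhere);
  planted variants get AC = round(af·AN), others draw AC ~ Binomial(AN, af).
* **Clinical:** PSA ~ LogNormal(μ=3, σ=1.2) ng/mL, ISUP ~ categorical
  (15, 1, 1, 33, 50)/100, age ~ N(71, 7) clipped to 45–92; metastasis ~
  Bernoulli(logit⁻¹(−7.0 + 1.2·log10(PSA+1) + 0.7·ISUP + 1.2·each gene
  indicator)), with six model genes carrying VUS at carrier probability
  0.2 each. The per-gene effect (1.2 on the log-odds scale) is chosen so
  the gene signal is detectable from a single ~100-patient training
  cohort.
* **Determinism:** all randomness flows from one seed through named
  sub-streams (planted, background, clinical, reference, VUS model, QC),
  so regenerating one artifact never perturbs the others, and the same
  seed reproduces byte-identical files.

A separate **recovery benchmark** (`recovery_planted()`) plants 15 strong
signals (carrier probability 0.04, reference AC ≈ 0; twelve in novel
non-DDR genes, three in DDR genes) among 21 frequency-matched nulls placed
in well-known, previously reported genes. The default (study-matching)
plant cannot support high per-seed detection sensitivity because a
singleton-level variant (carrier probability 0.008) is absent from a
100-patient cohort in ~45% of seeds; the benchmark conditions are the
planted conditions under which recovery guarantees are stated: ≥95%
sensitivity and ≤5% null false positives at FDR ≤ 0.05 over 200 seeds, and
exact recovery of the twelve novel genes when significance is pooled over
both cohorts (per-gene miss probability ~2×10⁻⁵).

Clinical-coefficient recovery is assessed by averaging estimates over eight
replicate cohorts of n = 2,000: a single fit's intercept has a sampling SD
of ≈ 0.16 under these conditions, so the ±0.2 recovery band is a statement
about bias, which averaging isolates from single-draw noise.

What the generator does **not** model: linkage disequilibrium, sequence
context and mutational signatures, relatedness, batch effects, genotype
uncertainty, population stratification within the cohort, or correlated
carrier status across genes. Passing recovery tests therefore demonstrates
the correctness of the statistical machinery under the planted model, not
robustness to those real-data phenomena.

## Degenerate inputs and tie-breaks

* All-zero 2×2 tables have no odds ratio (error); zero-margin Fisher
  tables give p = 1.
* Empty variant lists return empty results with a warning, not an error.
* A variant whose carriers are absent from the roster is an error (roster
  mismatch indicates corrupted inputs).
* ORA requires the query to be contained in the universe; sets are
  intersected with the universe before testing; k = 0 gives p = 1.
* Constant model columns are dropped with a warning before fitting.
* Recurrent-variant counting is per distinct patient (carrier sets).

## Known limitations

* The default evidence assigner is intentionally shallow; realistic
  classification requires an external annotation pipeline supplying
  evidence codes per variant.
* Enrichment is per-variant only; no gene-level burden collapsing
  (SKAT/CMC-style) is provided.
* The reference is treated as a fixed external count table; no
  case-control matching or ancestry adjustment is performed.
* The novel-gene definition depends entirely on the completeness of the
  supplied known-gene list.
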