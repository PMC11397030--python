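# Methods

## The problem

A clumping+thresholding (C+T) polygenic score uses three ingredients: a
discovery GWAS (per-variant effect `β_j` on the log-odds scale and p-value
`p_j`), an LD reference panel, and a target panel that limits which
variants can actually be scored. When the target platform lacks a
discovery variant — and lacks any well-correlated substitute — the score
silently loses information. `pgscov` measures that loss at two
resolutions: per top hit, and genome-wide.

## Single-variant coverage

A hit list is matched against an "available" variant set (an array
manifest pre-QC, the surviving measured variants post-QC, or the
high-quality imputed set). Matching uses chromosome+position first and
rsid as a fallback; rsid-only matches are flagged, since they usually
indicate a genome-build difference, and no liftover is attempted. A
missing hit is rescued by a proxy when some reference-panel variant
within ±500 kb on the same chromosome has r² ≥ 0.80 with it and is itself
available; among eligible proxies the highest r² wins, ties broken by
physical distance, then position. Coverage counts (direct, direct+proxy)
are stage-agnostic: the same computation runs at every pipeline stage with
a caller-supplied label.

LD is the squared Pearson correlation of dosages over pairwise-complete
samples — the standard estimator for (possibly imputed) array data. A
haplotype-EM r² was considered and deliberately left out: on unphased
dosage data the dosage correlation is what scoring pipelines themselves
use, and the proxy decision threshold (0.80) is far from the regime where
the two estimators disagree materially.

## The genome-wide coverage metric

Let `R` be a comprehensive reference panel of `n` individuals (the
intended real-data choice is the 498 unrelated European-ancestry 1000G
samples; the panel is configurable). Two C+T scores are computed with
identical machinery:

* **full**: clump the summary statistics on `R`'s LD, threshold at `t`,
  score the `R` individuals;
* **target-restricted**: first drop every summary record absent from the
  target platform's variant list, then clump on `R`'s LD, threshold at
  `t`, score the same `R` individuals.

The metric at threshold `t` is Pearson's correlation between the two
`n`-vectors. Pearson (not Spearman) because the two scores are linear
functionals of overlapping dosage sets and empirically sit on a straight
line; the suite asserts this self-consistency. The central contract: the
target cohort contributes **only its variant list**. Its genotype values,
sample size and allele frequencies never enter, so the metric isolates
platform coverage from cohort composition.

Degenerate thresholds (empty or constant target score) are reported as
`undefined`, never as 0 — an absent score is not a score with zero
information. A negative correlation is theoretically possible under
pathological restriction and is reported as computed, with a warning,
rather than clipped into the nominal [0, 1] range.

The default threshold suite is 5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.10,
0.20, 0.50, 1.0.

## The C+T engine

Clumping is the literal greedy procedure: repeatedly promote the unclaimed
variant with the smallest p-value (ties: chromosome, then position) to
index status, then claim every unclaimed variant on its chromosome within
±`clump_window_bp` at r² ≥ `clump_r2`; stop when no unclaimed variant has
p ≤ `p1`. Defaults `clump_r2 = 0.10`, window ±250 kb, `p1 = 1.0` — the
PLINK clump defaults, which is what scoring pipelines that do not state
parameters effectively use. The result is deterministic and independent of
input row order.

Scoring: `score_i = Σ_j β_j · e_ij` where `e_ij` is the effect-allele
dosage after orientation. Allele matching yields `same` (effect allele is
the panel ALT), `flip` (effect allele is the panel REF; `e = 2 − d`),
`ambiguous` (A/T or C/G pairs, whose strand cannot be resolved without
frequency heuristics — excluded by default and counted), or `mismatch`
(never scored). Only biallelic SNPs enter, and when the panel carries
imputation info, only variants with info > 0.80. Missing dosages are
mean-imputed to twice the effect-allele frequency (the PLINK `--score`
convention); an omit-with-renormalisation policy is available.

## QC cascade

Fixed filter order, each applied to the matrix surviving the previous
step: (1) sample call rate (missing fraction > 0.03 drops the sample),
(2) variant call rate (> 0.05), (3) MAF (kept iff ≥ 0.05), (4) HWE exact
test (dropped iff p < 1e-5), (5) info (kept iff > 0.80). Samples are
filtered before variants because MAF and HWE depend on the surviving
sample set. Boundary semantics are literal: MAF keeps equality, HWE drops
strictly below, info keeps strictly above. An optional sample mask lets
MAF/HWE be computed within one ancestry group while the whole panel is
filtered; sex-check/relatedness/divergent-ancestry exclusions are accepted
as a precomputed list rather than re-derived.

The HWE test is the exact conditional test: given the minor-allele count
`r` among `2n` alleles, the probability of `h` heterozygotes is summed
over all `h` (same parity as `r`) whose conditional probability does not
exceed that of the observed table. The distribution is built with the
standard stable ratio recurrence
`P(h+2)/P(h) = (r−h)(2n−r−h) / ((h+2)(h+1))`, vectorised, normalised in
log space. Fractional (imputed) dosages are rounded to hard genotype calls
for the HWE count; a mid-p variant is implemented behind a flag but off by
default. The test suite verifies the p-value against an independent
closed-form log-factorial enumeration for every genotype table with
n ≤ 200.

## Ancestry classification

Targets are pooled with anchor samples of known ancestry, mean-imputed,
standardised per variant by `(d − 2p)/√(2p(1−p))`, and decomposed by SVD;
PC signs are arbitrary, so every downstream rule uses only anchor-derived
intervals/distances and is sign-invariant (tested). Two classifiers are
exposed and deliberately not composed, since their interaction is a
judgement call best left to the analyst: anchored k-means (centroids
initialised at anchor-group means, one deterministic Lloyd run, tol 1e-8,
≤300 iterations) for cluster diagnostics, and the authoritative
European/non-European rule — European iff PC1 and PC2 each lie within the
closed interval [min − 1.96·sd, max + 1.96·sd] of the European anchors'
corresponding components. "Within" is taken as inclusive at the
endpoints.

## Synthetic data generator

The generator reproduces the statistical structure the method assumes, not
human demography. Per LD block, site frequencies are Uniform(0.05, 0.5)
and `n_founders` founder haplotypes are drawn; each individual's two block
haplotypes are copies of random founders with per-site flip probability ε.
Small founder pools give strong within-block LD; blocks are independent
(1 Mb gaps, far beyond every window default). The phenotype is quantitative
with `n_causal` additive effects ~ N(0, effect_sd²) plus N(0, 1) noise,
and "discovery" statistics are per-variant marginal OLS slopes with
t-test p-values; the odds-ratio column is `exp(β)` purely for format
compatibility. A quantitative trait replaces case-control logistic
association deliberately: the C+T machinery is agnostic to the effect
scale, and OLS gives closed-form marginal statistics that can be verified
against their sampling distribution. Arrays are uniform random subsets of
given density; "imputation" assigns hidden variants info ~ Uniform(0.5, 1)
and shrinks their dosages toward 2× allele frequency in proportion to
(1 − info).

Defaults (the conditions the tests and the acceptance script run at):
20 blocks × 25 SNPs, 8 founders, ε = 0.01, 600 samples (the real cohorts
motivating the method span ~630–910), 25 causal variants, effect sd 0.2,
array density 0.5. Problem sizes in individual tests are scaled to what
each property needs (e.g. 150–500 variants for oracle comparisons).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic minor-allele-frequency spectra and
rare variants, recombination-map-driven LD decay within blocks,
cross-block (long-range) LD, case-control ascertainment, genotyping batch
artefacts, population structure within the cohort (ancestry tests use
separately constructed frequency-shifted populations), and real imputation
machinery. Conclusions about *relative* information loss across array
densities and thresholds transfer; absolute metric values do not.

One global seed drives named substreams (panel / phenotype / array / info)
so stages can be re-run independently yet reproducibly; identical seeds
give byte-identical CLI outputs.

## Numerical choices and degenerate inputs

* r² is clipped at 1.0 against floating-point overshoot; constant dosage
  vectors make LD undefined (an error for the direct API, "not a proxy" /
  "not claimed" in search and clumping).
* Clump and proxy orderings specify full deterministic tie-breaks
  (p-value, then chromosome, position; r², then distance, position).
* Missing dosages are NaN — a sentinel outside [0, 2], never a value.
* Multi-allelic VCF records are split into one biallelic row per ALT by
  default (droppable by flag); downstream scoring restricts to biallelic
  SNPs anyway.
* Monomorphic variants: MAF 0, HWE p 1.0, undefined LD, dropped from PCA.
* All report floats print at 4 decimals (values below 1e-3 in scientific
  notation to keep threshold columns legible); NaN prints as `NA`.

## Known limitations

Single-threaded `O(hits × window)` proxy search and `O(m²)` worst-case
clumping are adequate for hit lists and tens of thousands of variants, not
for multi-million-variant genome-wide clumping; the engine is exact, not
optimised. No BGEN/PLINK-bed native input (convert to VCF). No liftover.
Alternative PGS derivations (continuous-shrinkage or Bayesian methods) are
out of scope; the metric is defined for C+T selection.
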