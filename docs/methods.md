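# Methods

## Overview

`dosecnv` chains six stages: sample coverage QC → RPKM/ZRPKM
normalisation → SVD denoising → run-length CNV segmentation →
frequency/recurrence filtering with inheritance classification →
expression-dosage integration, with Wilson intervals on every summary
proportion. This note records the modelling assumptions, the defaults and
why they hold, and what the synthetic cohort does and does not emulate.

## Depth model and calling

Read-depth CNV detection assumes that, after removing probe length and
library size (RPKM) and systematic cross-sample structure (SVD), the
residual per-probe deviation of one sample from the cohort is
proportional to its copy number: expectation scales by copy/2, so a
heterozygous deletion sits near −0.5 and a single duplication near +0.5
of a probe's typical depth before standardisation.

Numerical choices:

- **ZRPKM** uses the sample (n−1) standard deviation; probes with median
  RPKM < 1.0 are masked (too shallow to standardise), as are zero-variance
  probes (masked with a warning, never divided by zero). Masked probes
  are NaN in the matrices and break calling runs.
- **SVD denoising** computes the full SVD and zeroes the leading S
  singular values (default S = 7, configurable; S = 0 is the identity).
  The residual has zero projection on the removed left singular vectors.
  S is capped at the matrix rank bound and rejected beyond it.
- **Segmentation** takes maximal runs of consecutive unmasked probes at
  |score| ≥ 1.5 with length ≥ 3 probes, per sample and chromosome. The
  call interval is exactly the probes' footprint. No smoothing is
  applied, so per-probe dropouts fragment runs — which is also why
  single-probe events are invisible at min_probes = 3, mirroring the
  known failure mode of exome read-depth callers on single-exon CNVs.
- **Sample QC** (applied before normalisation) fails a sample only when
  all three hold: < 80% of targets at ≥ 20×, mean < 30× and median < 30×.
  The source description of this rule reads as a conjunction; a
  disjunction mode is available by flag for stricter screening.

## Filters and inheritance

- The 80% rule for population-common CNVs is one-way (fraction of the
  call covered), so a small call inside a large common CNV is flagged;
  reciprocal mode is a flag. Boundaries are exactly as quoted: MAF ≥
  0.01 (inclusive), study size > 40 (strict), overlap ≥ 0.8 (inclusive),
  recurrence > 10 carriers (strict). All are parameters.
- Recurrence clusters same-type calls by single-linkage at ≥ 50%
  reciprocal overlap and counts distinct individuals (probands and
  parents both count). `common` takes precedence over `recurrent` and is
  never overwritten, making the two filters commute and both idempotent.
- Inheritance matching uses ≥ 50% reciprocal overlap with same type;
  when both parents match, the maternal label is chosen and logged.
- Duo de novo inference: over SNPs inside the deletion where the proband
  is hemizygous, a site is incompatible when the genotyped parent is
  homozygous for a different allele. ≥ 2 incompatible sites (the
  min_informative default, guarding against a single genotyping error)
  yield `de_novo_inferred`; zero incompatible with ≥ 2 compatible
  homozygous-parent sites yield `on_missing_parent_haplotype`; anything
  else is `ambiguous`. Heterozygous parent sites are uninformative. A
  deletion that removed the *missing* parent's transmitted haplotype is
  genuinely unresolvable by this method and stays unresolved — only
  events that removed the genotyped parent's contribution can be proven
  de novo.

## Expression dosage

Gene Z-scores are standardised over *all* samples at once (cases plus
controls), so a case's outlier score is measured against the mixed
cohort reference. Genes with median count < 1 are masked as not
detectably expressed. A gene-call pair is a dosage outlier when both
|expression Z| > 2 and |CNV score| > 2 and the signs agree (the sign
requirement is a flag); the CNV score of a pair is the call's mean
SVD-ZRPKM, matching the call's own summary statistic. Direction
concordance is the Pearson correlation between expression Z and call
sign (−1 deletion, +1 duplication) over usable pairs; it is symmetric
under global sign flips, and degenerate one-sign designs return NaN with
a warning.

## The synthetic cohort

The generator emulates the data structure this analysis assumes, at a
desk scale chosen so the full pipeline runs in seconds:

- 8 trios + 6 duos + 4 singletons (40 samples) over 2000 probes on four
  chromosomes (200 bp targets every 1 kb); `SimConfig.study_profile()`
  switches to the 98/72/20 family mix of a full cohort.
- Depth: counts are Poisson around mean_depth × exp(batch) × copy/2 with
  a gamma multiplier (negative-binomial-like overdispersion,
  `depth_noise`). The batch term is multiplicative low-rank structure
  (rank `n_batch_factors`, scale `batch_sd`) — the nuisance signal the
  SVD stage must strip.
- CNVs: Poisson-many per proband (`cnv_rate_per_sample`), spans uniform
  over `cnv_probe_span_range` probes, copies from {1, 3} by default
  ({0, 4} available), inherited from a random parent or de novo
  (`de_novo_fraction`), optionally copied from a frequent
  common-database record (`common_cnv_fraction`).
- Expression: gene counts are gamma-Poisson around per-gene means with
  CV `expr_cv`; a gene responds to dosage (counts scaled by copy/2 in
  carriers) with probability `responder_fraction` = 0.8 — most, but not
  all, genes in a CNV respond. Responder status is gene-intrinsic, so
  parent and child carrying the same event perturb the same genes.
- Genotypes: SNPs inside every duo-proband deletion, Mendelian-
  consistent with the deleted haplotype, error-free by default
  (`genotype_error_rate` exercises the informative-site guard).

### Desk-profile calibration

Three effects bite at 40 samples that vanish in cohorts of hundreds, and
the defaults are set accordingly (chosen once, by design analysis):

1. A single carrier inflates its probes' cross-sample variance by
   0.25/(n−1) — negligible at n = 460, large at n = 40. Overlapping
   events from *different* samples therefore mask each other, so the
   generator places independent events without cross-sample overlap;
   deliberately recurrent loci (common-database draws, inherited events)
   still share probes.
2. The removed SVD subspace must hold batch structure, not copy-number
   signal. With a weak batch term the top singular values sit at the
   random-matrix noise floor and the removed components mix in long CNV
   patterns, halving their shift. Rank 1 at `batch_sd` = 0.05 keeps the
   batch component well separated from the floor while discarding only
   1/40 of the sample space.
3. Duplications carry ~1.5× the carrier Poisson jitter of deletions at
   equal |shift|, so mid-length duplication runs fragment first. Spans
   default to 5–20 probes with `depth_noise` = 0.001 and
   `cnv_rate_per_sample` = 1.5 (the full-cohort event density of ~18
   CNVs per exome over ~190k targets is far sparser per probe; the desk
   rate keeps enough events to measure recovery).

These magnitudes are gentler than real capture data, where stronger
batch structure and overdispersion are compensated by hundreds of
samples. Passing the recovery tests therefore shows the machinery is
correct at an equivalent signal-to-noise operating point, not that any
particular real cohort would achieve the same sensitivity.

### What the generator does not emulate

GC/mappability bias, probe-length variation, X-chromosome dosage (no
sex-aware depth by default), mosaic copy states, genotype dropout in
deep deletions, linkage between SNP sites, and expression covariates
(ancestry, cell-line artefacts). None of these are needed by the stages
under test, and all would make desk-scale recovery strictly harder
rather than change the algorithms.

## Statistics

Wilson score intervals use the normal quantile at (1 + confidence)/2
computed numerically (not a hard-coded 1.96), no continuity correction.
Bounds are exactly 0 and 1 at k = 0 and k = n. The test suite verifies
the closed form against numeric inversion of the score test for every
(k, n) up to n = 200 at 10⁻⁹, and against an independent library
implementation. Callset matching is greedy one-to-one on descending
reciprocal overlap within (sample, type) strata, ties broken by leftmost
start — deterministic and order-independent.

## Known limitations

- The caller reports probe-footprint intervals; breakpoints between
  probes are not refined.
- Sensitivity/false-call rates quoted by the tests are properties of the
  synthetic desk profile (see calibration above).
- Recurrence counts individuals via calls present in the callset;
  carriers whose call was missed upstream are not counted.
- The duo inference assumes error-free hemizygous genotypes by default;
  with genotyping error the min_informative threshold trades sensitivity
  against false de novo labels.
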