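# Methods note

This note records the statistical model implemented by `igaseq`, the default
parameter choices and their rationale, the scope of the synthetic cohort
generator, and the numerical conventions the tests pin down.

## Data model

A cohort consists of an ASV count table (strains × samples, non-negative
integers) and per-sample metadata: `subject_id`, `group` (`control`,
`ms_baseline`, `ms_6mo`), `fraction` (`presort`, `iga_pos`, `iga_neg`),
`timepoint` (`baseline`, `month6`), and the covariates `age`, `sex`, `bmi`
and `steroid_use` (`none` / `within_1mo` / `within_2_3mo`, collapsed to a
binary `steroid` indicator for modelling). `(subject, fraction, timepoint)`
is unique and controls exist only at baseline.

## Filters

- **Sample depth**: a sample is retained only if its total count is
  *strictly greater than* 2474 reads; removals are reported with depths.
- **Detection**: a strain is detected in a sample when its relative
  abundance is *strictly greater than* 1e-5. The same threshold defines the
  prevalences entering the coating score.
- **Prevalence**: a strain enters an analysis when detected in at least 10%
  (inclusive) of the relevant samples — all study samples for the coating
  analysis, per fraction for the differential analyses.

## IgA-Coating Score (ICS)

`ICS = log2((p+ + c)/(p− + c))` with pseudocount `c = 1e-5`, where `p+` and
`p−` are detection prevalences among a group's IgA+ and IgA− samples. The
pseudocount bounds the score at ±log2(1 + 1/c) ≈ ±16.6 when a strain is
ubiquitous in one fraction and absent from the other.

Inference conditions on subjects: only subjects contributing both sorted
fractions are used, and the null hypothesis — coating carries no
information — makes each subject's (IgA+, IgA−) detection pair
exchangeable. The test statistic is the ICS itself; the null distribution
swaps each pair independently with probability 1/2. With `n` subjects there
are `2^n` swap patterns: when `2^n ≤ 4096` they are enumerated exactly,
otherwise 999 seeded Monte-Carlo swaps are drawn and `p = (b + 1)/(B + 1)`.
Permuted statistics within 1e-12 of the observed value count as ties in the
observed tail, keeping the test valid under discreteness. The test is
one-sided for preferential coating; negative-ICS strains are never flagged.
Benjamini–Hochberg q-values are computed per group, and the default flag is
`p < 0.05` with `ICS > 0`.

## Community statistics

- **Shannon index** on relative abundances with the natural logarithm,
  treating `0 log 0 = 0`.
- **Bray–Curtis** dissimilarity is computed on arcsine-square-root
  transformed relative abundances, which stabilises the variance of
  proportions before the distance.
- **PERMANOVA** partitions the Gower-centred inner-product matrix
  `G = J(−½D²)J` sequentially: covariates (`age`, `sex`, `bmi`, `steroid`)
  are fitted before `group`, so the group sum of squares is the marginal
  contribution beyond the confounders. The pseudo-F for group uses the
  residual from the full model, and significance comes from 999 unrestricted
  row permutations of the distance matrix with the add-one rule. This
  sequential hat-matrix construction is written in-house because available
  Python PERMANOVA implementations do not support covariate adjustment; the
  no-covariate case is cross-checked against scikit-bio in the tests.

## Differential abundance and prevalence

- **clr transform**: zeros are replaced by 1.2e-5 (non-zero entries
  untouched), then `clr_i = ln x_i − mean_j ln x_j` per sample. The
  transform is applied to the full strain panel; models are then fitted on
  the prevalence-filtered subset.
- **Cross-sectional model**: per strain, OLS of clr abundance on a group
  indicator plus `age`, `sex_male`, `bmi` and `steroid`, with the group
  coefficient, its t-statistic and p-value reported.
- **Paired model**: for subjects sampled at baseline and month 6, the
  random-intercept model is fitted in its exact conditional form — OLS on
  within-subject differences, with between-subject covariates mean-centred.
  On balanced complete pairs without covariates this reproduces the paired
  t-test exactly (pinned to 1e-9 in the tests); a mixed-effects fit is used
  only as an approximate cross-check because its Wald inference differs in
  finite samples.
- **Prevalence contrasts**: 2×2 Fisher exact tests (scipy) on detection
  counts; the test suite validates them against an exact rational-arithmetic
  enumeration for all margins up to 12.
- **Display fold change**: `log2` of the ratio of arithmetic mean relative
  abundances (plus the clr pseudocount), reported alongside the clr
  estimate because clr coefficients are not fold changes.
- **Multiplicity**: Benjamini–Hochberg within each family; differential
  results are flagged at `q < 0.10`.

## Synthetic cohort generator

The generator is a parametric model of the three-fraction design, defaulting
to the emulated study's structure: 42 controls, 43 cases at baseline, 19 of
them re-sampled at month 6, three fractions each (312 samples), 300 strains.

Per strain `j`: a log-scale typical abundance `mu_j ~ Normal(0, 1.5)` and a
baseline detection probability `pi_j ~ Beta(0.8, 1.6)` (right-skewed, so
most strains are rare — matching the sparsity of strain-level tables). Per
subject and strain, a latent intensity `lambda ~ Gamma(shape 0.8)` with mean
`exp(mu_j + planted effects)` is shared across that subject's fractions, so
fractions are correlated within subject as they are in real data. Planted
effects: *abundance* effects add a natural-log fold change to the intensity
mean for a group; *coating* effects split an offset across the sorted
fractions (+off/2 on IgA+ detection logit, −off/2 on IgA−); *prevalence*
effects shift detection probability directly (clipping to [0, 1] is logged
in the ground truth). Detection is Bernoulli per sample; detected
intensities are closed to proportions and sequenced as a multinomial draw at
a log-normal depth (median 20 000, log-sd 0.35). Month-6 samples reuse the
subject's latent intensities with `ms_6mo` effects applied, giving genuine
within-subject pairing. Covariates are drawn inert by default (no
association with group) so null calibration can be tested; a
`confound_strength` switch induces confounding deliberately. An optional
missing-at-random dropout rate removes sorted-fraction samples, reflecting
the incomplete designs seen in deposited data. Flow-cytometry summaries
(percent IgA-coated per subject) are Beta draws with a group shift.

Everything is seeded: `substream(seed, name)` derives independent named
generator streams (for example `"cohort"`, `"ics:control"`,
`"permanova:presort"`), so adding a stage never perturbs another stage's
draws and identical seeds give byte-identical pipeline outputs.

**Scope**: the generator models counts given a design; it does not simulate
reads, sequencing error, taxonomy, or longitudinal drift beyond the single
treatment timepoint.

## Resolved ambiguities

- "Depth exceeding 2474" is read as a strict inequality; a sample at exactly
  2474 is removed.
- The detection threshold 1e-5 is applied uniformly, including to the
  prevalences inside the ICS.
- The permutation null swaps within subject (paired design), not across
  subjects.
- Steroid use is modelled as a binary indicator (any recent use), with the
  three-level factor retained in the metadata.
- The paired analysis uses the exact conditional (differences) form rather
  than an iterative mixed-model fit, making results deterministic and
  exactly reproducible.

## Limitations

- The ICS permutation test is conservative at small subject counts because
  the swap distribution is discrete; with fewer than ~5 informative subjects
  the smallest attainable p may exceed 0.05.
- Measured power for the clr cross-sectional model at the default design:
  sign recovery is essentially certain and `p < 0.05` in ≈ 93% of runs for a
  ln-fold effect of 2.0 on a ubiquitous strain at 42 + 43 subjects, but only
  ≈ 30% at 12 + 12 — small pilot cohorts should not expect calibrated
  recovery of moderate effects.
- PERMANOVA permutes rows unrestrictedly; with strong covariate imbalance a
  restricted permutation scheme would be more exact.
- clr coefficients are relative to the per-sample geometric mean; a planted
  log-fold `delta` on one of `D` strains appears as `delta(1 − 1/D)`, and
  single-strain effects induce small opposite-signed shifts in all others.
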