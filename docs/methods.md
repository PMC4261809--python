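# Methods

This note documents the statistical procedures spikescan implements, the
synthetic cohort it is validated against, the numerical choices that are
not obvious from the code, and the known limitations of both.

## Study design being modelled

A retrospective longitudinal case-control cohort: 76 infants at elevated
genetic risk for type 1 diabetes, sampled roughly monthly from about 4–6
months to 2.2 years of age (~1,400 stool samples at the generator's
defaults), of whom 29 later develop persistent islet autoantibodies
("cases") and 47 do not ("controls"). Taxon read counts come from 16S
amplicon sequencing; the analysis starts from taxon-by-sample count
tables and never touches raw reads.

## Preprocessing

Order is fixed and asserted by the pipeline: depth filter → rarefaction →
relative abundance → rank aggregation → reliability cutoff.

- **Depth filter.** Samples with fewer than 10,000 reads are excluded
  (strict `<`).
- **Rarefaction.** A single multivariate-hypergeometric draw per sample to
  exactly 10,000 reads — subsampling without replacement, one draw rather
  than an average over repeats, with the seed recorded in provenance.
  Repeat-averaging would shrink variance below what downstream rank tests
  assume.
- **Rank aggregation.** Lineages use `p__/g__/s__` prefixes; unresolved
  levels aggregate into explicit `unclassified-<parent>` buckets so no
  mass is dropped. Aggregation preserves per-sample totals to 1e-9.
- **Reliability cutoff.** Technical-replicate dispersion rises sharply as
  relative abundance falls. `derive_cutoff` bins within-replicate-group
  coefficients of variation on a 20-point log-abundance grid, enforces a
  monotone (non-increasing in abundance) envelope, and returns the
  smallest abundance whose smoothed CV is at or below the threshold
  (default 0.35). At the generator's replicate-noise defaults the derived
  cutoff sits at ~1% relative abundance, and 1% is the pipeline default.
  Retention uses the median across samples (robust, and consistent with
  how dominant-taxon filters are usually drawn); the count of *all*
  pre-filter taxa, `m_total`, is carried forward for the FDR correction.

Tables are TSV throughout (taxa × samples with a lineage column; metadata
with sample/subject/age/group/platform/replicate-group columns).

## Differential abundance

- **Mann–Whitney U.** Exact enumeration when both groups have ≤ 8
  observations and no ties; otherwise the tie-corrected,
  continuity-corrected normal approximation. The asymptotic path is also
  implemented as a row-vectorised kernel so bootstrap loops stay fast;
  it is bit-identical to the scalar path and cross-checked against
  scipy in the tests.
- **Subject-balanced bootstrap.** Subjects differ widely in sample counts,
  and repeated samples of one subject are correlated, so the plain
  all-samples test is anticonservative whenever sampling frequency is
  unbalanced. Each bootstrap iteration draws exactly *k* samples per
  subject (default *k* = 1; without replacement when the subject has
  enough samples, with replacement otherwise), the Mann–Whitney p is
  computed on the draw, and the arithmetic mean over 100 iterations is
  reported. When every subject contributes one sample the procedure
  reduces exactly to the plain test. The averaged-p statistic is mildly
  conservative (averaging pulls extreme iterations toward the middle);
  the acceptance suite quantifies both this and the inflation it removes.
- **FDR.** Benjamini–Hochberg step-up computed as if `m_total` hypotheses
  existed, with the untested (filtered) ones at p = 1 — equivalently,
  denominator ranks run over `m_total`. Significance gate: adjusted
  p < 0.001.
- **Age × abundance interaction.** Logistic regression of case status on
  abundance, age, and their product (standardised covariates); the
  interaction is tested by a 1-df likelihood-ratio chi-square against the
  no-interaction model. ANOVA-style Wald tests were the main alternative;
  the LRT was chosen as the better-behaved small-sample test. Perfect
  separation triggers a weakly ridge-penalised refit, flagged in the
  result.
- **LOESS trajectories.** Degree-1 local regression with tricube weights
  on a nearest-neighbour bandwidth (span default 0.75), evaluated on a
  50-point grid covering the age range inclusive; the pointwise SE comes
  from the equivalent-kernel norm times a residual variance estimate.
  Written in-package because no installed library exposes grouped LOESS
  with an evaluation grid and SEs.
- **Covariate balance.** Contingency chi-square per covariate (durations
  binned), NA for single-level covariates, with a low-expected-cell flag.

## Sliding-window temporal scan

Samples are age-ordered; from every `step`-th position (default 10) a
window grows until it holds 98 samples *after* truncating each subject to
its 2 samples nearest the window midpoint. (The truncated size depends
only on per-subject tallies, so the extent is found by a counting pass
and truncation applied once.) Windows with fewer than 20 case or 20
control subjects are discarded and counted. Within a window each subject
becomes one median profile; case and control profiles are compared by a
bootstrap-averaged Mann–Whitney test in which every iteration resamples
an equal number of subjects (the smaller group's size) from each group
with replacement. Flags are reported unadjusted at 0.05 and 0.01 — the
scan describes *when* a difference exists rather than re-testing *whether*
it exists. `locate_peak` returns the minimum-p window, earliest on ties.
Age intervals are half-open `[start, end)` in days; one month = 30.44
days everywhere.

With ~1,400 samples from 76 subjects at 36-day intervals, 98-sample
windows span roughly 45–50 days. A sparser real cohort (fewer samples per
subject) would make the same windows proportionally wider; realized
widths are reported per window.

## Species calibration and qPCR

Short reads resolve only the merged *B. dorei/vulgatus* group; a 93-sample
subset re-sequenced with longer reads resolves both species. Per species,
a Poisson GLM with log link regresses species pseudo-counts (fraction ×
rarefaction depth, unrounded) on `log(group pseudo-count)`, with
observation weights proportional to group abundance, mean-normalised —
low-abundance measurements are the unreliable ones, so they are
down-weighted. In the noiseless proportional case the fit is exact
(intercept = log share, slope = 1, deviance R² = 1). Fit quality is
deviance R² (1 − residual/null deviance), the appropriate generalisation
of R² for a GLM. Predictions are clipped to `[0, group abundance]`; a
group abundance of zero imputes zero. Fitting is per species (the
post-hoc check that shares sum to ~1 is reported, not imposed).

qPCR triplicates pass QC when their coefficient of variation is ≤ 0.3 (a
conventional reaction-repeatability bound; the source protocol reports
discarding high-variance triplicates without a number). Concordance is a
Poisson regression of mean copy number on relative abundance with a
quasi-Poisson (Pearson) scale so overdispersion does not fake
significance; the verdict is "concordant" when the slope is positive with
p < 0.01.

## Seroconversion prediction

One feature per subject: median abundance of the focal taxon over that
subject's samples inside the age window (default 186–368 days ≈ 6.1–12.1
months). Leave-one-subject-out logistic regression with balanced class
weights and standard L2 shrinkage (C = 1) produces one held-out score per
subject; AUC is computed over the pooled scores by the Mann–Whitney
identity (ties count ½) with the Hanley–McNeil SE, and significance is
the full-data 1-df likelihood-ratio test. Two numerical points matter:
without class balancing, the training prevalence depends on the held-out
subject's own label and drives the null AUC to ~0 instead of 0.5; and
pooled leave-one-out scores retain a mild pessimistic null bias (each
fold's slope tilts slightly against its excluded subject) that shrinkage
damps but does not remove — null cohorts average AUC ≈ 0.47 rather than
0.50. Effect-size rankings are unaffected.

## The synthetic cohort

The generator is the package's test bed; its defaults are the study
conditions.

- **Schedules.** First sample at ~150 ± 18 days, then intervals of 36 ±
  11 days (7-day floor) until 803 days. Cases draw a seroconversion age
  from N(16.8, 10.9) months (the spread is the subject-level SD implied
  by a reported mean ± SE over 29 cases), truncated to fall after the
  first sample.
- **Composition.** 20 species across 5 phyla, Bacteroides-dominated, as
  Dirichlet-multinomial: expected fractions perturbed per subject by
  mean-one lognormal tilts (SD 0.3), Dirichlet precision 1/overdispersion
  (default overdispersion 0.02), read depths lognormal around 50,000.
- **The spike taxon.** Expected fraction = logistic colonisation ramp
  (controls plateau 5% at t50 ≈ 500 d; cases 12% at ≈ 400 d — cases are
  several-fold higher across all ages) **plus** a Gaussian bump. Each
  subject's bump has width 50 d, timing N(231, 30) d and a mean-one
  lognormal amplitude factor (SD 1.0); amplitudes are rescaled so the
  *population mean* curve passes exactly through 17.3% (cases) and 0.18%
  (controls) at 231 days ≈ 7.6 months. Timing and amplitude heterogeneity
  are essential, not decorative: without them every case separates
  perfectly from every control near the peak, the windowed rank test
  saturates at its exact p-floor across ±60 days, and the located peak
  becomes a tie-breaking artifact. They also mirror the obvious biology —
  infants start solid food at different times and spike to different
  degrees.
- **Replicates.** Each technical replicate perturbs the sample's
  empirical composition with multiplicative lognormal noise whose SD is
  `scale · sqrt(0.01/abundance)` (capped at 2), then redraws reads
  multinomially — noise equals `scale` at 1% abundance and grows below
  it, reproducing the sharp low-abundance variance rise that motivates
  the 1% cutoff.
- **Fine-platform subset.** The 93 samples richest in the group get the
  group count split binomially at the *B. dorei* share (default 0.75)
  into two species rows.
- **qPCR.** Copies ∝ relative abundance × constant total load with
  between-sample (SD 0.3) and within-triplicate (SD 0.1) lognormal noise;
  6 samples get 8× triplicate noise so the CV filter has something to
  discard.
- **Null mode** equalises the case curve to the control curve exactly;
  everything else (subject effects, noise) is unchanged.

What the generator does **not** emulate: taxonomic misassignment, primer
and copy-number bias, compositional interactions beyond closure,
age-varying sequencing depth, dropout/withdrawal, and any real covariate
structure (covariates are balanced by construction unless imbalance is
injected). Passing tests therefore demonstrate that the statistics do
what they claim under the modelled data structure — not that the
biological findings would replicate in new cohorts.

## Validation problem sizes

The acceptance suite runs 50 null and 50 effect cohorts at full cohort
shape (76 subjects, 20 taxa), 200 reduced cohorts (15 + 15 subjects) for
the bootstrap-balancing demonstration, 50 calibration replicates at 93
pairs, and exhaustive enumeration oracles for the elementary statistics
(all tie-free Mann–Whitney arrangements to n = 6 per group; 1,000 random
vectors each for the B-H and AUC oracles). Unit tests use smaller Monte
Carlo sizes where the acceptance suite already covers the property at
scale.

## Known limitations

- **Peak localisation vs. detection power.** At the published effect
  sizes the case/control separation near the peak is strong enough that
  the windowed Mann–Whitney sits at or near its exact p-floor over a
  ±50–60 day region, so the minimum-p window's age carries cohort-level
  noise of roughly ±55 days (SD) even though its median is unbiased at
  ~231 days. Weakening the injected effect tightens localisation but
  costs all-samples detection power; the two cannot both be made
  near-certain at this cohort size with k = 1 subject-balanced testing.
  The acceptance suite asserts both properties at face value and the
  localisation check is expected to fail at its 90% bar under the default
  (faithful) effect sizes.
- The bootstrap-averaged p is not a p-value in the strict uniform-null
  sense (it is conservative); it matches the procedure it reimplements.
- The windowed scan reports unadjusted flags by design; an FDR across
  windows would be a different (and stricter) question.
- LOSO-CV AUC retains a small pessimistic null bias (above).
- BIOM input is not supported; tables are TSV.
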