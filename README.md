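# spikescan

Statistical pipeline for detecting and timing taxon abundance spikes in
longitudinal case-control microbiome cohorts, built around the design of
infant gut 16S studies of islet autoimmunity: subjects sampled roughly
monthly through infancy, a case group that later seroconverts, and a
dominant *Bacteroides* species group whose relative abundance surges in
cases months before the first autoantibody appears.

The package answers four questions about such a cohort:

1. **Which taxa differ between cases and controls?** A Mann–Whitney *U*
   test averaged over subject-balanced bootstrap iterations (each
   iteration draws the same number of samples per subject, so
   heavily-sampled subjects cannot dominate), with Benjamini–Hochberg FDR
   adjustment computed against the *total* number of taxa — including
   those removed by the abundance-reliability filter — at α = 0.001.
2. **When do they differ?** A sliding-window scan: age-ordered windows of
   98 samples (at most two per subject, subjects collapsed to median
   profiles, windows with fewer than 20 case or 20 control subjects
   discarded), each tested by a bootstrap-averaged Mann–Whitney test; the
   minimum-*p* window localises the spike.
3. **Which species is it?** Short amplicons resolve only a merged
   two-species group. A weighted Poisson regression (log link, weights ∝
   group abundance) calibrated on a paired long-read subset splits the
   group, imputes per-species abundances cohort-wide, and a Poisson
   regression of qPCR copy numbers on relative abundance confirms the
   spike is an absolute increase.
4. **Does it predict case status?** Leave-one-subject-out cross-validated
   logistic regression on each subject's median in-window abundance,
   scored by AUC — the probability a random case outranks a random
   control — with no subject ever present in the model that scores it.

Everything runs against a first-class **synthetic cohort generator**
(`spikescan.simulate`) that emulates the study design end-to-end:
Dirichlet-multinomial compositions, a logistic colonisation ramp plus a
Gaussian age bump pinned to published effect sizes (case 17.3% vs control
0.18% at 7.6 months), per-subject spike timing and amplitude
heterogeneity, technical replicates with abundance-dependent noise, a
species-resolved platform subset and qPCR triplicates.

## Worked example

```bash
python examples/02_preprocess_and_differential.py
```

```
depth filter: 3 samples below 10,000 reads excluded
reliability cutoff: 19 of 20 species retained (all 20 still count in the FDR correction)

significant at adjusted p < 0.001: 1 taxa
  p__Bacteroidetes;g__Bacteroides;s__dorei_vulgatus
    adjusted p = 1.71e-05, case-higher (case median 0.088 vs control 0.009)
```

Three shallow samples fall to the 10,000-read depth filter; one species
falls below the 1% median-abundance reliability cutoff but still counts
among the 20 hypotheses in the FDR correction; and the injected
*Bacteroides dorei/vulgatus*-like group — and only it — is called
significantly case-elevated. `examples/03_window_scan.py` then times the
spike (minimum-*p* window at ~6.5–8 months in this cohort),
`examples/04_species_calibration.py` recovers the 75% *B. dorei* share of
the group with deviance R² ≈ 1.0 and a concordant qPCR slope, and
`examples/05_predict_seroconversion.py` reports the cross-validated AUC
(≈1.0 at the generator's default effect size).

The same stages are available as a CLI for shell use:

```bash
spikescan run-all --seed 7 --out run1        # simulate + full analysis
spikescan simulate --seed 7 --cases 29 --controls 47 --out cohort/
spikescan report run1
```

`run-all` is deterministic: one master seed feeds named per-stage child
streams, and rerunning with the same seed reproduces every output file
byte for byte.

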