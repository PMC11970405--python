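# Methods

## The measurement model

A PTC drug test quantifies drug effect as the change in total cluster area
of a well between two photographs.  The chain implemented here is:

1. **Segmentation** (`imaging`): global Otsu threshold with automatic
   polarity detection (clusters are the minority phase; brightfield
   clusters are darker than background), hole filling, morphological
   opening (disk radius 3 px by default, small relative to the 40 μm
   cluster floor at the 1–2 μm/px scales the assay uses), 8-connected
   component labeling.  No watershed splitting: the assay seeds wells
   sparsely (30–50 clusters per well), so touching clusters are rare, and
   the downstream statistic is a whole-well area sum that is insensitive to
   merge/split errors.
2. **Measurement**: area = pixel count × (pixel size)²; equivalent
   diameter = 2·√(area/π).  "Diameter" is operationalized as the
   equal-area circle's diameter because clusters are near-spherical.
3. **Filter**: clusters retained iff equivalent diameter > 40 μm
   (exclusive boundary — the rule is stated as "exceeding"; an inclusive
   switch exists for sensitivity analysis).  The filter is applied
   independently at t₀ and t₁: the viability formula uses whole-well area
   sums, so no cluster-to-cluster tracking is needed or attempted.
4. **Scoring** (`scoring`): p_Ai = S_t1/S_t0 per replicate, pA = mean over
   replicates (3 by default), effective iff pA < 0.7 (boundary value 0.7 is
   not effective).  Negative-control viability pNC < 0.9 discards the whole
   sample test (boundary 0.9 passes).  pA is not control-normalized; a flag
   offers it for exploration only.  Replicates with S_t0 = 0 are excluded
   individually and logged; a drug–concentration group needs ≥ 2 usable
   wells to be scored, otherwise it is dropped and reported.

## Ec calibration

ER(c) = fraction of assay-set samples with pA < 0.7 at concentration c,
computed per concentration over all samples measured there (no
imputation for missing sample×concentration combinations).  Ec is the
tested concentration minimizing |ER(c) − ORR|, ORR being the drug's
clinical objective response rate supplied as configuration.  Ties break
toward the lowest concentration — the calibration is an operating point,
and when two concentrations match the clinic equally well the lower one
stresses the assay (and any off-target biology) less.

## Reproducibility QC

Per drug–sample pair, CV = sample SD (n−1) / mean of the replicate
viabilities; summaries are the mean CV and the fraction of pairs with
CV < 0.50 (strict).  The resampling analysis draws, B = 1,000 times, an
unordered pair of distinct replicate columns uniformly at random (with
replacement across draws) and correlates the two vectors across all pairs,
Pearson and Spearman (average ranks for ties).  This "two replicate
vectors over the same pairs" reading is the only one under which a
correlation across hundreds of drug–sample pairs is defined; a
`columns+rows` mode that additionally bootstraps the row set is exposed
as an alternative without endorsement.

## Clinical concordance

The analysis unit is the treatment, not the patient.  RECIST labels are
merged to three classes on input (CR+PR, SD, PD).  Accuracy modes:
`CRPR_vs_PD` drops SD (the 8-vs-12, 20-treatment analysis) and
`CRPR_vs_SDPD` counts SD with PD as resistant; in both, a treatment is
concordant when CR/PR is called effective or the resistant class is called
not effective.  SD treatments are counted as resistant with no
pathological-response override (that arithmetic matches the published
overall-accuracy denominator).

ROC analysis scores each treatment by −pA so that AUC > 0.5 means lower
viability predicts response.  AUC is computed by pairwise counting,
P(score₊ > score₋) + ½P(tie), which equals trapezoidal integration of the
empirical ROC curve (asserted against an independent trapezoidal oracle in
the tests).  The confidence interval uses DeLong's placement-value
variance; when the observed AUC is exactly 0 or 1 that variance collapses,
so a stratified bootstrap (2,000 resamples, percentile, seeded) takes over
with a warning.  Mann–Whitney comparisons use the exact null when both
groups have n ≤ 8 and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity corrections; an all-identical pooled
sample returns p = 1 with a warning.  Fisher's exact test is two-sided by
hypergeometric enumeration; batches of p-values are Benjamini–Hochberg
adjusted.  Continuous viabilities can be z-standardized ((x−mean)/SD,
ddof = 1) for cross-cohort modeling.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the study's stated operating conditions:

- **Growth** is piecewise multiplicative: area compounds at `exp_rate`
  (default 0.15/day) until `plateau_start_day` (default 7), stays flat for
  `plateau_duration_days` (default 10, within the 5–25 day plateau PTCs
  show), then decays at `decline_rate`.  Wells seed 40 clusters (the
  30–50 range) with log-normal initial diameters around 80 μm.
- **Measurement noise** is multiplicative log-normal (ratios must stay
  positive).  Default per-measurement CV 0.16, so a t₁/t₀ ratio of two
  independently noised measurements spreads with CV ≈ √2·0.16 ≈ 0.23, the
  replicate spread real panels show.
- **Dose response** is a Hill curve (potency, slope, max kill, per-sample
  sensitivity multiplier).  The analysis never fits one; the generator only
  needs monotone dose dependence, and a Hill form is the field's default.
- **Replicate matrices**: `noise_cv` is defined as the *expected observed*
  replicate CV — the mean of per-row sample CVs, which is the quantity QC
  reports summarize.  Because the sample SD of n draws underestimates the
  population SD by c4(n) (≈ 0.886 at n = 3), the generator inflates the
  underlying population CV by 1/c4 so that the observed mean CV matches
  the knob.  Row-level true viabilities are log-normal (log-SD 0.6 around
  0.7), wide enough that replicate correlations are informative.
- **Cohorts**: log-viability is normal within each RECIST class; the
  default locations (0.40 / 0.85 / 1.30 for CR/PR / SD / PD, log-SD 0.35)
  were set once to reproduce the qualitative class separation of the
  validation cohort — CR/PR well below the 0.7 cutoff, SD straddling it,
  PD above.  `CohortSpec.for_target_auc(θ)` places CR/PR vs SD+PD at the
  binormal gap √2·σ·Φ⁻¹(θ), making θ the single concordance knob;
  `perfect_separation()` forces accuracy and AUC to 1 by construction.
  Default composition: 60 treatments, 8/40/12, 33/60 prospective.
- **Determinism**: all randomness flows from one integer seed through
  `numpy.random.SeedSequence`; assay wells use substreams keyed by
  (sample, drug, concentration, replicate), so identical seeds reproduce
  tables and images bit-for-bit and adding wells never perturbs existing
  ones.

What the generator does *not* model — and hence what passing tests cannot
show about real data: cluster self-assembly and shape irregularity (disks
only), uneven illumination and debris in micrographs, immune or stromal
compartments, sample-to-well allocation from the 500–50,000 clusters a
sample yields, batch effects between chips, and any mechanistic link
between genotype and drug response.  Concordance results on synthetic
cohorts validate the statistical machinery, not the biological claim.

## Numerical choices and problem sizes

- Viability recovery on noise-free assays is exact to machine precision;
  tests assert 1e−9.
- Segmentation closure targets: 1% total-area error on noise-free wells,
  5% at contrast-to-noise 5 with 2 px blur (512² images, 1 μm/px, disks
  25–120 μm).
- Recovery tests use 200 simulated cohorts of n = 60 (AUC targets 0.6 /
  0.75 / 0.9, tolerance 3·SE), 200-sample panels for Ec calibration, and
  337×3 replicate matrices; these sizes keep the full suite under a
  minute while leaving Monte-Carlo error well inside the asserted
  tolerances.
- Tie-breaks: Ec ties → lowest concentration; waterfall ties → stable
  input order; Spearman ties → average ranks.
- Degenerate inputs: constant images segment to zero regions; constant
  viability vectors cannot be standardized; zero-baseline wells raise a
  named error and are excluded upstream of all statistics.

## Known limitations

- The 2×3 contingency and accuracy statistics treat each treatment as
  independent even when several come from one patient, mirroring the
  assay's own reporting; no clustering correction is applied.
- DeLong's variance assumes independent observations and is anti-
  conservative under within-patient correlation.
- The segmentation is deliberately simple (global threshold); confluent
  wells or strong vignetting would need a local-threshold or watershed
  extension before the area sums are trustworthy.
- Ec calibration reproduces the *procedure*; recovering a published Ec
  table requires the original assay-set raw data, which is out of scope.
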