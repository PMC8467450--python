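# Methods

## The activity model

`pathscore` infers, per sample, the probability that a signalling pathway's
driving transcription complex is actively transcribing its target genes. The
model is a tree-structured Bayesian network with three layers:

1. **Pathway node** — a single binary root, *active* vs *inactive*, with
   prior P(active) = 0.5 by default (uninformative; overridable).
2. **Gene layer** — one binary node per target gene ("is the gene being
   transcribed"), linked to the root by a conditional probability table.
   Defaults: P(transcribed | active) = 0.9 and
   P(transcribed | inactive) = 0.1 for up-responsive genes, mirrored for
   down-responsive genes, overridable per gene through the panel file. The
   symmetric defaults keep the prior's influence interpretable; nothing in
   the inference requires symmetry.
3. **Evidence layer** — the log2 intensity of each microarray probeset
   interrogating a gene, modelled as a two-component Gaussian: mean
   `mu_high` when the gene is transcribed, `mu_low` when silent, shared
   standard deviation `sigma`. Soft Gaussian evidence is the default; an
   optional hard mode binarises each probeset at the midpoint
   `(mu_low + mu_high)/2` with a fixed 5% evidence error rate, provided for
   sensitivity analysis because hard thresholds are brittle on continuous
   intensities.

Genes are conditionally independent given the root and probesets given
their gene, so the root posterior is exact: each gene's transcription state
is summed out locally,

    P(active | x) ∝ P(active) · ∏_g Σ_{t∈{0,1}} P(t | active) · ∏_p N(x_p; μ_t, σ_p),

normalised against the corresponding inactive product. All computation runs
in log space; the test suite checks the result against brute-force
enumeration of the full joint over every latent configuration.

The posterior is reported three ways: as a probability, as log2-odds
`log2(p/(1−p))` capped at ±20 (the cap keeps degenerate, noiseless evidence
finite), and as a **0–100 activity score**: an affine map of the log2-odds
between two anchors, clipped to [0, 100].

## Calibration

`calibrate` fits the evidence layer from labelled training profiles
(≥2 samples per label):

* `mu_high` / `mu_low` are the label-conditional means per probeset
  (active-labelled samples supply the transcribed mean for up-responsive
  genes, inactive-labelled samples for down-responsive genes);
* `sigma` pools the within-label sums of squares and is floored at 0.05
  log2 units so that constant training columns cannot produce a degenerate
  density;
* the normalization anchors are the minimum and maximum capped log2-odds
  observed on the training samples themselves, so training samples span the
  full 0–100 range and cohort scores are comparable across studies (scores
  outside the anchors clip rather than re-scale).

A probeset whose calibrated means run against its declared direction is
flagged with a warning but kept as fitted — silently swapping means would
hide label noise from the user. The `pseudocount` argument shrinks both
label means toward the pooled mean with weight equal to the pseudocount
(default 0, i.e. plain means); it exists to stabilise calibration on very
small training sets. A probeset whose two means coincide contributes a
likelihood ratio of 1 and leaves the posterior at the prior.

Missing probesets are an error everywhere — scores silently computed on
partial evidence would not be comparable, so nothing is imputed.

### The shipped panel

The default panel holds sixteen canonical NFκB target genes (NFKBIA,
TNFAIP3, BIRC3, CCL2, CXCL8, ICAM1, IL6, TNF, TRAF1, BCL2A1, BCL2L1, PLAU,
PTGS2, VCAM1, SOD2, CD40) mapped to one or two synthetic probeset ids each.
It reproduces the *method* — the panel content and every parameter are open
and configurable; it is not, and does not attempt to approximate, any
proprietary calibrated assay, so absolute scores from this package are not
comparable to scores from commercial implementations of the same idea.

## The synthetic-data generator

The generator exists so every pipeline stage can be tested against known
truth without downloading any external dataset. It emulates, on the log2
scale with additive Gaussian noise:

* **Cross-sectional cohorts** — per sample a binary latent pathway state
  (Bernoulli at the cohort's activity rate, default 0.2, the commonly cited
  fraction of myeloma patients with NFκB-activating lesions); per panel
  gene a transcription state drawn from the model CPT; probeset intensity
  `mu_low + effect_size·[transcribed] + N(0, noise_sd)` with defaults
  effect_size = 2.0 log2 units and noise_sd = 0.5; 200 background genes of
  pure noise around a 6.0 baseline.
* **Calibration sets** — drawn from the model's own emissions with the
  transcription state fixed at its modal value given the label, so that at
  zero noise calibration reproduces the generating emissions exactly (a
  closed loop used by the tests).
* **Longitudinal studies** — default 8 patients × 4 timepoints (diagnosis,
  first-line induction, second-line induction, maintenance). The latent
  activation probability rises by `activity_shift_at_relapse` (default
  0.6) at the relapse timepoints (the last two), reflecting the strong,
  near-universal per-patient increase such designs report. Patients carry a
  Gaussian baseline offset (sd 0.3 log2 units) shared by all their samples,
  which is what makes paired analyses genuinely better than unpaired ones.
* **BCL-2 family genes** — BCL2A1, BCL2L1, BCL2 (NFκB-regulated) and
  BCL2L10, MCL1, BCL2L2 (NFκB-independent) are always generated by a
  dedicated rule: background level plus an explicit per-patient multiplier.
  A configurable fraction of patients (default 0.625, i.e. 5 of 8, chosen
  as the smallest design matching the granularity such 8-patient analyses
  report) receive a `fold_change_magnitude` (default 4-fold) BCL2A1
  multiplier at the relapse timepoints. The number of upregulated patients
  is `round(fraction·n)` drawn without replacement, so the realised
  fraction is exact rather than Bernoulli and the fold-change classifier
  can be tested for exact recovery. With `couple_bcl2_to_pathway=True` the
  three NFκB-regulated members additionally follow the latent state like
  panel genes, which is the scenario where differential BCL2A1 correlates
  with differential target expression.

Because the family rule overrides the panel rule, synthetic studies are
scored with `simulation_panel()` — the default panel minus the family
genes. This keeps the activity score independent of the family genes'
configured regulation: without the separation, the BCL2A1 multiplier would
leak into the score and a "no activity shift" configuration would not be a
true null for the paired score comparison.

**What the generator does not emulate:** probe-affinity physics, CEL-level
data, normalization artefacts (RMA/MAS5), correlated gene programs beyond
the single latent state (given that state, gene transcription states are
conditionally independent), dropout/missingness, and clinical covariates.
Passing tests therefore demonstrate correctness of the inference and
statistics under the stated generative assumptions — not that the shipped
default panel reproduces any published cohort's absolute scores.

## Statistics

* Group summaries report median, quartiles (linear interpolation between
  order statistics — the convention is carried in the output since plotting
  software differs), min, max, n.
* Multi-group comparison is classical equal-variance one-way ANOVA
  (`scipy.stats.f_oneway`) with Tukey HSD adjusted pairwise p values
  (`scipy.stats.tukey_hsd`; Tukey–Kramer harmonic-mean adjustment for
  unequal group sizes). When every observation is identical the comparison
  short-circuits to F = 0, p = 1 rather than the undefined 0/0 ratio.
* The paired relapse-vs-diagnosis comparison defaults to a one-sided
  sign-flip permutation test on the mean paired difference (2000
  resamples). With binary-ish latent states the score differences are
  strongly bimodal, where the permutation test is exact-level under the
  exchangeable null; a classical paired t test is available via
  `method="ttest"`.
* Fold change between paired samples is `2^(followup − baseline)` of log2
  values, with strict `>` at the threshold (default 2-fold): a patient at
  exactly 2.0-fold is not called upregulated.
* Differential correlation regresses Δtarget on Δanchor per target gene
  (`scipy.stats.linregress`) and reports Pearson R, the two-sided p, and
  the slope. No multiple-testing correction is applied across the target
  panel; the table is descriptive and should be read with that caveat. A
  target with zero Δ variance is reported as R = 0, slope = 0, p = 1 by
  convention; a zero-variance *anchor* is an error.

## Problem sizes and numerical choices

* Replicate experiments (`pathscore.experiments`) use 100 replicate studies
  of 20 patients for detection power and 400 replicates for the type-I
  rate; replicate studies simulate only the two compared timepoints and no
  background genes, since neither enters the score or the test — a pure
  cost saving chosen to keep the full analysis re-runnable in minutes on a
  laptop.
* Log-odds cap ±20 (log2 units), sigma floor 0.05, quartiles by linear
  interpolation, permutation tests seeded and with 2000 resamples, every
  generator seeded explicitly; identical spec + seed is bit-identical.
* Ties in `map_probesets` max-mean selection resolve to the first probeset
  in matrix order.

## Known limitations

* The gene-layer CPTs are defaults, not fitted: calibration estimates the
  evidence layer only. Fitting CPTs would require transcription-state
  ground truth that labelled calibration cohorts do not carry.
* Score anchors come from the calibration cohort's observed log2-odds
  range; a study whose evidence is far stronger than the calibration data
  saturates at 0/100 (visible with the default synthetic conditions, where
  evidence across 22 probesets is strong and scores are near-binary).
* QC is a missingness/scale gate only; array-level quality metrics are out
  of scope.
* The GEO series-matrix reader handles the plain-text dialect (quoted ids,
  `!`-prefixed metadata); it does not download or decompress anything.
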