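# Methods

This note documents the models, algorithms, defaults and numerical
choices implemented in `erpstates`, and what the synthetic-data tests do
and do not establish about real infant EEG.

## Data model

An ERP is a channel × sample matrix in microvolts, sampled at `fs`
(default 500 Hz) over an epoch of −200…794 ms relative to stimulus
onset (498 samples). All topographic computations operate on
average-referenced data. Times are in milliseconds; sample 0 is the
epoch start; all analysis windows are inclusive at both ends, and a
window is the *set of samples* whose time falls inside it, so a window's
length is `count × (1000/fs)` ms. The post-stimulus part of the default
epoch contains 398 samples (796 ms); the microstate feature window
300–794 ms contains 248 samples (496 ms).

Three stimulus conditions are modelled — face with direct gaze (FD),
face with averted gaze (FA) and a scrambled non-social control (Noise) —
crossed with three cohort groups: no family history of autism and no
diagnosis at 3 years (noFH-noASD), family history without later
diagnosis (FH-noASD) and family history with later diagnosis (FH-ASD).

## Nc component features

Nc mean amplitude is the mean of the region-averaged waveform over the
300–800 ms window; peak latency is the time of the most negative sample
in the same window, ties resolved to the earliest sample. When the
800 ms bound exceeds the recorded epoch (which ends at 794 ms in the
default design) the window is clipped to the epoch and the clip is
logged once — this reconciles the classic Nc window with the epoch used
by the topographic analyses without silent error. Region membership
(frontal-left/central/right) is configuration, not code; a generic
block montage ships as a default and any montage can be supplied as a
JSON channel→region map. Region averages are computed on
average-referenced data for consistency with the topographic stages.

## Microstate analysis

**Normalisation.** Each sample topography is average-referenced and
scaled to unit GFP. Spatial correlation between topographies is the
Pearson correlation across channels (equivalently the cosine of the
normalised vectors). Correlations are **signed**: in evoked (time-locked)
data, polarity carries component identity — the Nc is a negativity — so,
unlike resting-state microstate practice, no absolute value is taken. A
config switch (`ignore_polarity`) provides the rectified variant for
sensitivity analyses.

**AAHC.** Clustering starts from every sample as its own cluster and
repeatedly dissolves one cluster, reassigning its members to the
remaining cluster with the highest spatial correlation; centroids are
the polarity-aligned member mean renormalised to unit GFP, and clusters
are weighted by squared GFP in all explained-variance bookkeeping.
Two refinements stabilise the greedy hierarchy (both active in map
selection; `aahc_cluster` alone defaults to the pure greedy form):

* at low cluster counts (≤ 2 + twice the largest requested k) the
  dissolution criterion is the minimum *GEV loss* — the cluster's
  contribution minus what its members recover when re-homed — rather
  than the minimum contribution. The plain rule systematically
  sacrifices genuine weak-field short-lived states while keeping
  near-duplicate copies of strong states;
* a correlation k-means polish (full reassignment + centroid update,
  up to `refine` passes) is interleaved at those counts and applied to
  every captured solution, since greedy agglomeration strands boundary
  samples.

**Choosing the number of maps.** Maps are learned from the reference
group's (noFH-noASD) grand average in the FD condition over 0–794 ms.
For each of 10 random half-splits of the reference subjects, one
agglomeration of the training grand average yields solutions at every
k in the candidate range (default 2–7), and the mean GEV of the
held-out subjects' ERPs under those maps is recorded. Because template
fitting takes a per-sample argmax, held-out GEV is weakly monotone in
k, so the step from k−1 to k is judged by a randomization test on what
the *new* map explains: the candidate least correlated with the k−1
templates is added with the k−1 assignments held fixed, and its GEV
gain is compared with the same gain after the residuals about the k−1
model are re-oriented by a shared random channel permutation and sign
flip (200 draws; p = (1+#{null ≥ observed})/201; split statistics are
aggregated by median for robustness to an occasional degenerate
training clustering). Walking k upward, the selected k is the last of
an unbroken chain of significant steps (α = 0.05); if the first step
already fails, the floor of the range is returned with a warning. The
exchangeable-residual null assumes spatially white residuals — true of
the default generator, approximate for real EEG (see Limitations).

**Fitting and features.** The selected maps, refit on the full
reference grand average, are used as templates for every subject and
condition: each in-window sample is labelled with the map of highest
signed correlation (ties to the lowest map index; flat samples carry
the previous label so occupancy stays conserved). Per map and
condition the features are the total labelled duration in 300–794 ms
(non-contiguous samples count; durations over maps sum exactly to the
window length) and the mean raw GFP over those samples (missing, and
imputed as 0 for modelling, when the map never occurs). A map absent in
more than 5% of subjects is dropped from the modelling feature set —
with the default generator exactly one of the four maps (expressed only
before 300 ms) is dropped, leaving sex, age, developmental level and
3 maps × 3 conditions × 2 measures = 21 features.

## Outcome prediction

**Categorical outcome** (diagnosis within the family-history group).
The family-history subjects are split 70/30 stratified by outcome
(train size = round(0.7·n), matching a 64/27 split at n = 91). Feature
subsets are binary masks evolved by a genetic algorithm — population
50, uniform crossover 0.8, per-bit mutation 1/p, elitism 2, tournament
selection, early stop after 20 stalled generations, 20 independent
evolutions — with fitness the ROC AUC of pooled out-of-fold decision
scores from a 10-fold cross-validated linear SVM whose class weights
are inversely proportional to class frequency. Standardisation uses
training-fold statistics only; folds and their standardisation are
fixed per run so fitness evaluations are cacheable. The *optimal set*
is the best mask over all evolutions; feature *incidence* is the
fraction of evolutions whose best fitness exceeded 0.75 AUC and whose
best mask contains the feature; the *high-incidence set* keeps features
with incidence > 0.80. Holdout evaluation refits the SVM 1000 times on
stratified bootstrap resamples of the training rows, thresholds
decision scores at 0, and reports AUC, sensitivity, specificity, PPV,
NPV and accuracy in percent as mean ± SD with 95% CIs averaged over
repetitions (Wilson intervals for proportions, Hanley–McNeil for AUC);
a metric with a zero denominator in a repetition is excluded from that
metric's mean with the exclusion counted. Significance against chance
is a one-sided label-shuffle test with add-one correction,
p = (1+#{null ≥ observed})/(n_shuffles+1).

**Dimensional outcome** (VABS Socialization). Elastic-net regression
with leave-one-out outer cross-validation; per outer fold the mixing
parameter (l1 ratio 0.1…1.0) and penalty strength (10 log-spaced values
spanning 10⁻⁸…10) are tuned by 10-fold × 10-repeat inner CV minimising
RMSE, ties resolved toward the sparser model (larger penalty, then
larger l1 ratio). Features are standardised inside each training set.
Two numerical safeguards keep the grid honest at both extremes: the
inner search first scans the practical range (alpha ≥ 10⁻³) at standard
solver tolerance and only re-evaluates the full grid at tight tolerance
when the best inner error is far below the outcome scale (a
near-noiseless fit, where solver error would otherwise scramble the
ranking among tiny penalties); and the final per-fold fit uses a
tolerance scaled to the inner error so the near-OLS limit is solved to
numerical precision without wasting iterations on noisy fits. Pooled
leave-one-out predictions give the RMSE and the relative error
(RMSE divided by the observed outcome range, in percent); the RMSE CI
is a percentile bootstrap (1000 resamples) over pooled prediction
pairs; coefficients are recorded per fold and a feature is
*always selected* when nonzero in every fold.

## Synthetic cohorts

The generator emulates the study design: groups of 40/72/19 subjects,
three conditions, 64 channels (any count works; 64 keeps tests fast) at
500 Hz. Four random average-referenced unit-GFP topographies with
pairwise |correlation| ≤ 0.5 are planted; the fourth is oriented to a
frontal negativity and plays the attentive (Nc-like) state. Each
group × condition has an ordered segment plan (map, duration, mean GFP)
whose durations fill the post-stimulus window; the FH-ASD group gets a
shorter, weaker attentive segment for faces, largest for direct gaze.
Per subject, segment sample counts are jittered by a rounded Gaussian
(SD 20 ms, clipped at zero, total conserved by adjusting the largest
segment) and segment GFPs by a multiplicative Gaussian (SD 0.1);
spatially white sensor noise (default SD 0.5 µV, appropriate for an
average of a few dozen trials) is added to every sample. Covariates are
drawn independently: sex (p = 0.5), age 184–351 days, developmental
level N(100, 15²). The continuous outcome is
intercept (100) + Σ β·(planted feature − cohort mean) + noise
(SD 10), clipped to the plausible 40–140 score range; default betas put
the signal on the attentive map's FD strength (5 per µV), its FD
duration (0.03 per ms) and sex (4), echoing a design in which brain
state strength relates to dimensional social skill and sex is a strong
covariate. The binary outcome is group membership (FH-ASD). Valid-trial
counts per condition are rounded N(25, 8²) clipped to 0–60, so the
≥10-trials inclusion rule removes a realistic few percent. Every output
is a deterministic function of the seed.

**What passing tests show.** Recovery tests demonstrate that the
implementation is correct under its own generative assumptions —
stable topographies with abrupt switches, spatially white noise,
linear outcome links. Real infant EEG has spatially correlated noise,
gradual topography transitions, inter-subject topography variability
and nonlinear outcome relations; passing these tests does not certify
performance under those conditions. The generator's optional spatial
smoothing of noise is deliberately off by default so that oracle
expectations stay exact.

## Problem sizes

Defaults are sized for a desk-scale run: map-count selection uses 10
half-splits × 200 randomizations (≈2–3 s for 40 reference subjects);
the GA at its defaults evaluates a few thousand cached fitness calls
per evolution; the full nested elastic net at n ≈ 120 runs in a few
minutes. The acceptance script runs the entire analysis, including
1000 classifier evaluation repetitions and a 999-shuffle test, in well
under half an hour on a single CPU.

## Known limitations

* The exchangeable-residual null in map-count selection is calibrated
  for spatially white residuals; with strongly correlated sensor noise
  it can become anticonservative. A TANOVA-style subject-permutation
  null would be the natural extension.
* Classifier repetition variability covers training-resample and split
  stochasticity, not re-running feature selection per repetition (a
  config flag could repeat the GA, at ~100× cost).
* Flat (zero-GFP) samples are labelled by carry-forward to preserve
  duration conservation; under heavy baselines a dedicated "unassigned"
  state would be more faithful but breaks the conservation invariant.
* EDF support is read-only and assumes potentials in microvolt-scaled
  EEG channels.
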