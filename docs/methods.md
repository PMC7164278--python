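# Methods

`hybci` implements a hybrid EEG–fTCD brain–computer-interface decoder and a
probabilistic transfer-learning scheme that reduces how much calibration
data a new user must record. This note documents the model, the synthetic
cohorts it is validated on, the numerical choices, and what the validation
does and does not show.

## The decoding model

Each 10 s trial is a pair of recordings: 16-channel EEG sampled at
256 samples/s and a two-segment (left/right middle-cerebral-artery) fTCD
velocity envelope, here carried at 100 samples/s. Trials belong to one of
three conditions (two tasks and a fixation baseline); decoding is posed as
three binary problems per paradigm (task1 vs baseline, task2 vs baseline,
task1 vs task2), each over 100 trials (50 per class).

**Feature extraction** is modality- and paradigm-specific:

* *Motor imagery EEG* — common spatial patterns (CSP). Per trial the
  trace-normalized scatter `S = R Rᵀ / tr(R Rᵀ)` is averaged within class;
  the generalized eigenproblem `Σ₊ w = λ Σ₋ w` is solved as
  `eigh(Σ₊, Σ₊ + Σ₋)`, which directly yields `λ⁺ ∈ [0, 1]` with
  `λ⁺ + λ⁻ = 1` and a whitening transformation
  (`Wᵀ(Σ₊ + Σ₋)W = I`). Features are the log sample variances of the trial
  filtered with `f` eigenvectors from each end of `W` (columns sorted by
  `λ⁺` descending). Default `f = 1` (2 features): with one lateralized
  oscillatory source per class, the first/last filters carry nearly all
  class information, and small filter sets keep the projection stable on
  the ≤ 90-trial training sets the transfer study cares about. `f` up to 8
  is supported.
* *Flicker (SSVEP) EEG* — template matching. Per class, the 16 electrode
  templates are the electrode-wise means of that class's training trials; a
  trial's 32 features are the maxima over all lags of the cross-correlation
  with each template, normalized by the product of the Euclidean norms of
  trial segment and template (so a trial equal to its template scores
  exactly 1). Raw, un-normalized correlation is available via
  `xcorr_mode="raw"`.
* *fTCD (both paradigms)* — a 5-level db4 discrete wavelet decomposition of
  each segment (symmetric padding); per sub-band (D1..D5, A5) the mean,
  variance (1/(n−1)), skewness and non-excess kurtosis, 24 features per
  segment, 48 per trial. Sub-band moments are zeroed when the sub-band
  variance underflows (< 1e−12). Segments shorter than 32 samples are
  rejected; truncated segments below the strict 5-level length simply carry
  boundary-dominated coarse bands.

**Selection and projection.** fTCD features (and SSVEP template features)
pass a two-sided Wilcoxon rank-sum filter at p < 0.05, learned on training
trials only; MI CSP features bypass selection (the 2f log-variances are the
designed feature set). Each modality's retained features are z-scored with
training statistics and projected by a linear SVM (C = 1) to a scalar
evidence score, sign-aligned with the problem's positive class. An empty
selection degrades to all-zero scores for that modality rather than
erroring; the fused decision then rests on the other modality.

**Evidence normalization.** Raw SVM decision values have an arbitrary,
dataset-dependent scale. Three decision-neutral steps make scores
comparable across folds, subjects and datasets (every step applies the same
monotone map to both classes, so fused decisions are unchanged):

1. evidence scores of training trials are computed **out-of-fold**
   (stratified 10-fold; the whole feature stage — CSP or templates,
   selection masks, scalers, SVMs — refit per fold), because
   training-set decision values are optimistically separated for any
   subject, which would erase the very separability differences the
   similarity measure must see;
2. each fold's scores are affinely mapped so its reference (negative)
   class sits at mean 0, spread 1, then re-anchored on the pooled
   out-of-fold reference scores (fold-train statistics are slightly
   optimistic);
3. scores are softly bounded at ±4 reference-noise units
   (`4·tanh(x/4)`), since larger separations are conclusive and their
   exact magnitude is estimation noise.

A trial's test-time evidence is the fold-ensemble average of normalized
decision values, so test scores live on the same scale as the training
scores the densities were fitted on. Training sets too small for folding
(< 4 trials in a class) fall back to self-scored evidences.

**Fusion.** Per class and modality a Gaussian-kernel KDE is fitted to the
training evidence scores, with Silverman's simple rule
`h = 1.06·σ̂·n^(−1/5)` (the robust IQR variant is available; the simple
rule is the default because the score distributions are deliberately kept
on a common scale, where the extra adaptivity of the robust rule only adds
variance). Intent is inferred by maximizing the fused class-conditional
likelihood under uniform priors, in the log domain with densities floored
at 1e−300:

* **A2** (equal weight): `p(e|x)·p(f|x)` — default for the flicker
  paradigm;
* **A3** (weighted): `p(e|x)^α · p(f|x)^(1−α)` — default for motor
  imagery, with α chosen on the 101-point grid 0.00..1.00 by stratified
  10-fold cross-validated accuracy on the training evidences (ties to the
  smallest α; fewer than 10 training pairs fall back to α = 0.5).

Exact likelihood ties resolve deterministically to the problem's first
class.

## Transfer learning

A subject is summarized by four class-conditional evidence densities
(2 modalities × 2 classes). Similarity between a new user (profiled from
its few training trials) and each prior user (profiled from its full 100
problem trials, with its own self-contained pipeline) is the sum of the
four Bhattacharyya distances between corresponding densities, each computed
by discretizing both densities on a shared 512-point grid (union of score
ranges padded by 3 bandwidths), normalizing to probability masses floored
at 1e−12, and evaluating `−ln Σ √(PᵢQᵢ)`. The printed-form variant
`−ln Σ PᵢQᵢ` is available for comparison (`form="printed"`). Profile
densities use a fixed bandwidth of 1 reference-noise unit rather than
per-sample Silverman bandwidths: on the common score scale a fixed
bandwidth makes the distance insensitive to the sampling noise of
per-density spread estimates, which otherwise dominates subject-to-subject
comparisons at 100 trials.

Candidates are ranked by ascending total distance (ties by subject id).
For k = 1..3 the current user's training trials are pooled with the top-k
candidates' trials and scored by stratified 10-fold cross-validated
accuracy of the fully refitted pipeline on the pooled set; the best k wins
(ties to the smallest; k = 0 can be admitted via `allow_k0`). The final
decoder is refitted on the pooled set — feature models, masks, SVMs, KDEs
and α included — and evaluated on the current user's held-out trials. With
an empty augmentation this is exactly the no-transfer (NTL) pipeline.

## Evaluation

For each subject (leave-one-subject-out: the rest of the cohort are the
prior users), training uses the first m trials in presentation order,
m ∈ {10, ..., 90}, testing the remainder; both modes are swept over trial
truncations of 1..10 s, and per training size the maximum over lengths is
reported, together with the cross-evaluated series (each mode at the other
mode's optimal lengths). ITR per selection is
`B = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))` — algebraically a KL
divergence against the uniform distribution, hence ≥ 0 with equality
exactly at chance — scaled to bits/min by `60/trial length`, with the
truncation length as the trial length.

Calibration reduction scans m upward: the reported m is the first size at
which a one-sided Wilcoxon signed-rank test (α = 0.05, zero-differences
split) no longer finds NTL-at-90 better than TL-at-m *and* the mean TL
accuracy at m is similar to or outperforms the mean NTL accuracy at 90,
with "similar" read as within one standard error of the paired
difference. The percentage then
averages per-subject `1 − (m·len_TL(i)) / (90·len_NTL(i))` with each
subject's shortest accuracy-maximizing trial length. If no m qualifies the
reduction is reported as 0%.

## The synthetic cohorts

No public recordings exist for this paradigm pair, so validation runs on a
generator that emulates the study conditions: cohorts of 10 subjects
(11 supported for the flicker paradigm), 150 trials of 10 s each in
randomized order, 50 per condition.

Per trial the EEG is 1/f background plus white sensor noise; MI task trials
add an 8–12 Hz band-limited source through a class-specific lateralized
spatial pattern (left-motor channels for task 1, right-motor for task 2),
flicker task trials add 7 Hz (task 1) or 17 Hz (task 2) sinusoids over
parietal channels. The fTCD envelope is a baseline flow level plus a
rectified-sinusoid cardiac component (~1 Hz), trial-to-trial flow drift
(common and per-side terms; the common term has a stable subject-specific
skew), white noise, and — on task trials — a sustained, lateralized
flow-level rise. Attention is modelled per trial: a lapse (probability =
subject's lapse rate) suppresses the task response in both modalities;
otherwise the response scales with a skewed lognormal engagement factor.
The hemodynamic response is mostly autonomic (gain 0.7 + 0.3·engagement),
the EEG response fully engagement-scaled.

Subjects differ in source amplitude, flow contrast, lapse rate, flow
drift, engagement variability and skew, spatial patterns, noise levels and
response laterality. The four parameters that dominate the evidence-score
geometry (amplitude, contrast, lapse rate, drift) are placed on a
randomized rank-1 lattice over their ranges, so a 10-subject cohort tiles
the space of user responsiveness the way a heterogeneous real cohort does
and no two non-clone subjects coincide in every dimension; the remaining
parameters draw independently. Clone pairs copy another subject's
parameters with 2% relative jitter. Amplitude and contrast ranges were
fixed once so that the no-transfer decoder at 90 training trials lands in
the 70–90% accuracy band typical of hybrid BCI studies; defaults are part
of the study conditions and are not tuned per experiment.

**What the generator does not model:** eye/muscle artifacts, non-stationary
drifts within a session, realistic EEG forward physics, volume conduction
between the task sources, or inter-channel noise correlation. Passing
statistical checks on these cohorts shows the pipeline's machinery behaves
as designed under its own assumptions; it does not certify performance on
human recordings.

## Study-scale problem sizes

The statistical checks run the full-scale pipeline (10 subjects, 150
trials, 10 s) but keep the sweep affordable by fixed design choices: 20
cohort seeds; similarity and transfer evaluated at the full 10 s length;
the TL-vs-NTL comparison at 10 training trials on three designated
subjects per cohort (one of them a clone member); the calibration-reduction
scan over all nine training sizes on two cohorts' pooled subjects. The
trial-length sweep (1..10 s) is exercised by the unit tests and available
through `TransferExperiment`; the headline study fixes 10 s because fTCD
wavelet statistics at 1–2 s truncations are boundary-dominated.

## Known limitations

* Subject similarity at 100 trials is intrinsically noisy: two independent
  sessions of the *same* subject have a nonzero profile distance
  (test-retest noise of out-of-sample separability estimates), which sets
  a floor on how reliably a planted near-identical subject can be ranked
  first among nine competitors. The design above (honest out-of-fold
  scores, reference-class normalization, bounded evidences, fixed profile
  bandwidth, space-filling cohorts) raises clone recovery from near-chance
  to roughly 4 runs in 5; perfect recovery would require either longer
  recordings or a cohort more heterogeneous than real BCI cohorts appear
  to be.
* The α grid search maximizes a cross-validated accuracy that is
  statistically flat in α whenever one modality dominates; the selected α
  is then arbitrary along the plateau (its fused accuracy is not).
* Template matching refits templates per fold during score projection,
  which is the dominant cost of the flicker path; the MI path caches trial
  scatter matrices and is roughly an order of magnitude faster.
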