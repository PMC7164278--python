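# hybci

Hybrid EEG–fTCD brain–computer-interface decoding with probabilistic
evidence fusion and cross-subject transfer learning.

## The problem

Brain–computer interfaces must be calibrated per user before they work:
each new user records labelled trials until the decoder is accurate enough,
which is burdensome precisely for the users BCIs are meant to help. `hybci`
implements a hybrid BCI that records 16-channel EEG together with
functional transcranial Doppler (fTCD, cerebral blood-flow velocity in the
two middle cerebral arteries) and a transfer-learning scheme that shrinks
the calibration requirement by borrowing trials from *similar* previous
users.

The decoding model, per binary selection problem (task 1 vs baseline,
task 2 vs baseline, task 1 vs task 2):

* **features** — CSP log-variances for motor-imagery EEG (generalized
  eigenvectors of the class covariances, `Σ₊w = λΣ₋w`), all-lag normalized
  template-matching correlations for flicker (SSVEP) EEG, and
  mean/variance/skewness/kurtosis of the six db4 wavelet sub-bands for
  each fTCD segment (48 features);
* **evidence** — Wilcoxon rank-sum feature selection (p < 0.05) and a
  linear SVM per modality project each trial to two scalar evidences
  (e, f);
* **fusion** — Gaussian-KDE class-conditional densities with Silverman
  bandwidths, fused as `argmax_x p(e|x)·p(f|x)` (assumption A2) or
  `argmax_x p(e|x)^α p(f|x)^(1−α)` (A3; α by grid search over 0..1,
  step 0.01, under cross-validation);
* **transfer** — a subject's four class-conditional score densities are a
  *profile*; subject similarity is the sum of the four Bhattacharyya
  distances `−ln Σ√(PᵢQᵢ)` between discretized profiles; the top-k most
  similar prior subjects (k ≤ 3, chosen by cross-validation) augment the
  new user's training set;
* **evaluation** — accuracy and information transfer rate
  `B = log₂N + P log₂P + (1−P)log₂((1−P)/(N−1))` over training sizes
  10..90 and trial lengths 1..10 s, plus the calibration-reduction
  percentage `mean_i [1 − m·len_TL(i) / (N·len_NTL(i))]` at the first
  training size m where transfer matches full-calibration no-transfer
  performance (one-sided signed-rank scan).

No public recordings exist for this paradigm pair, so the package ships a
first-class synthetic cohort generator (`hybci.synth`) that emulates the
study conditions — 10-subject cohorts, 150 randomized 10 s trials per
subject, CSP-separable motor-imagery EEG, 7/17 Hz flicker EEG, pulsatile
lateralized fTCD envelopes, per-subject responsiveness/attention traits and
planted near-identical "clone" pairs. See `docs/methods.md` for the model
and generator details.

## Worked example

```python
import hybci

cohort = hybci.generate_cohort(hybci.CohortConfig(
    n_subjects=4, seed=42, trials_per_condition=20, trial_seconds=4.0))

res = hybci.HybridDecoder.from_dataset(
    cohort[0], problem="task1-vs-baseline", seed=0).fit()
print(res.summary())
```

```
Hybrid EEG-fTCD decoder
===============================================
paradigm:            MI
problem:             task1-vs-baseline (+: task1, -: baseline)
n training trials:   40
fusion assumption:   A3 (alpha = 0.44)
CSP filters:         2f = 2; lambda+ ends: 0.619 ... 0.431
fTCD features kept:  4 / 48 (rank-sum p < 0.05)
KDE  EEG|baseline     h = 0.5466, n = 20
KDE  EEG|task1        h = 0.5999, n = 20
KDE fTCD|baseline     h = 0.5472, n = 20
KDE fTCD|task1        h = 0.4098, n = 20
training accuracy:   0.950
```

The summary reads: the decoder fused under the weighted assumption with
α = 0.44 (EEG weighted slightly below fTCD), the first CSP filter captures
62% of the task-class variance, 4 of 48 fTCD wavelet features were
significant, and the four fitted evidence densities have the shown
bandwidths. The transfer-learning study over the cohort:

```python
exp = hybci.TransferExperiment(cohort, hybci.PipelineConfig(seed=0))
out = exp.fit(train_sizes=(10, 20, 30), trial_lengths=(4.0,), seed=0)
print(out.summary())
```

```
Transfer-learning study (leave-one-subject-out)
=======================================================
paradigm / problem:  MI / task1-vs-baseline
subjects:            4

mean accuracy over subjects (max over trial lengths)
train size      TL       NTL
        10   0.833    0.567
        20   0.850    0.700
        30   0.850    0.800

calibration reduction: 66.67% (m = 10, N = 30)
```

With only 10 training trials, augmenting from similar subjects lifts mean
accuracy from 0.567 to 0.833 — already matching the no-transfer decoder at
30 trials, a 66.67% saving in calibration length on this toy cohort.
`out.performance` holds the tidy per-cell table and `out.plot()` the
accuracy/ITR curves.

## Command line

```bash
hybci synth --paradigm mi --subjects 10 --seed 1 --clone-pairs 0,3 --out cohort.h5
hybci profile --data cohort.h5 --subject S00 --problem task1-vs-baseline --out sim.csv
hybci tl-run --data cohort.h5 --subject S01 --problem task1-vs-baseline --train-size 10
hybci evaluate --config experiment.toml     # full sweep -> CSVs + plots
hybci report --performance results/performance.csv
```

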