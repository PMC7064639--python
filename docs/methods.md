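# Methods

This note records the models, conventions and numerical choices behind
`nirsbag`, and what the synthetic benchmarks do and do not show.

## Signal model and preprocessing

**Modified Beer–Lambert law.** Optical-density changes at two
wavelengths relate linearly to chromophore concentration changes:

ΔOD(λᵢ) = d · DPF(λᵢ) · [ε(λᵢ, HbO) ΔHbO + ε(λᵢ, HbR) ΔHbR]

with d the geometric source–detector separation (cm), DPF the
differential pathlength factor and ε the specific extinction
coefficients in 1/(mM·cm). `mbll_convert` solves the 2×2 system per
sample and channel pair; `hb_to_optical_density` is its exact forward
inverse, so round-trip error is at machine precision. The default
parameter set — 760/850 nm, ε = [[1.4866, 3.8437], [2.5264, 1.7986]]
1/(mM·cm), DPF = 6.0 at both wavelengths, d = 3 cm — is a documented
package convention for simulation and round-trip work, not a measured
constant set; real analyses should supply instrument-specific values.
Concentrations are always µmol/L, times always seconds.

**Band-pass filter.** A Butterworth band-pass of order 3 per pass
(0.01–0.09 Hz defaults) applied forward–backward (`sosfiltfilt`), i.e.
zero phase and 6th-order effective. The passband straddles the
task-locked hemodynamics while rejecting drift (below 0.01 Hz) and
cardiac (~1 Hz), respiratory (~0.25 Hz) and most Mayer-wave (~0.1 Hz)
oscillations. Edge handling is fixed for reproducibility:
odd-symmetric signal extension with pad length 3·(order + 1) samples.
Measured contract (asserted in tests): a 0.05 Hz sinusoid is retained
at ≥ 0.95 amplitude with zero sample lag; 1.0 Hz is attenuated by more
than 40 dB; DC is removed.

**Epochs, baseline, features.** Epoch windows are half-open [a, b) in
onset-relative time; onsets snap to the nearest sample of the
recording grid, so every epoch has the same length. An interval
[a, b) contains the grid samples with a ≤ t < b (counted by ceiling,
not rounding — at 12.5 Hz the 5-s window [5, 10) holds 63 samples).
Baseline correction subtracts the per-trial, per-channel mean over
[-1, 0) s and is idempotent. Features are temporal means of ΔHbO and
ΔHbR over [5, 10) and [10, 15) s — late windows because the response
peaks ~6–8 s after onset — ordered channel-major, HbO before HbR,
windows in order; the ordering is recorded in `feature_names` so
models are portable. No trial rejection stage exists: the pipeline
assumes motion-artifact-free input.

## Classifiers

**LDA / RLDA.** Class priors are empirical frequencies, class means
sample means, and Σ the pooled within-class covariance with divisor
N − K (unbiased; the divisor is a fixed documented choice). The
regularized covariance is the literal convex combination
Σ_γ = (1 − γ)Σ + γI. This target is not scale-invariant — γ = 0.1
means something different if features are rescaled — which is accepted
deliberately: window-mean fNIRS features share one unit (µmol/L).
Scores are the Gaussian equal-covariance discriminants; prediction is
argmax with ties to the lowest class index. At γ = 1 the scores
collapse to the identity-covariance closed form
log π_k − ½‖μ_k‖² + xᵀμ_k.

**Ledoit–Wolf shrinkage.** `ledoit_wolf_gamma` implements the analytic
optimal intensity toward the scaled identity target m·I,
m = tr(S)/d, with the standard plug-in estimates: δ² = ‖S − mI‖_F²/d,
b̄² = (1/n²)Σᵢ‖xᵢxᵢᵀ − S‖_F²/d, γ* = min(b̄², δ²)/δ², clipped to
[0, 1]; S uses divisor n on class-centered data (within-class
covariance is the relevant one for LDA). Zero empirical covariance
yields γ* = 1. The estimate matches
`sklearn.covariance.ledoit_wolf_shrinkage` to machine precision (the
sklearn routine is used only as a cross-check, never called by the
pipeline).

**Bagging ensemble.** N_learn bootstrap resamples of the full
training-set size with replacement (resample fraction 100%); one RLDA
weak learner with γ = 0.1 per resample; aggregation by plurality over
predicted labels, which in the binary ±1 encoding is exactly
sign(Σₙ sign(hₙ(x))). Design points:

- a resample that leaves any class with fewer than 2 members is
  redrawn, up to 100 times, then errors;
- an even vote split is resolved toward the lowest class index and
  flagged in the prediction record; odd N_learn (default 25) avoids
  binary ties altogether;
- multiclass problems vote over natively multiclass RLDA weak
  learners (plain LDA and the linear SVM baseline instead wrap
  one-vs-one, mirroring common strong-learner practice);
- the ensemble is fully determined by (features, N_learn, γ, seed);
  resample indices are stored and serialized for exact reload.

**Linear SVM baseline.** Features are standardized by training-fold
mean/SD (zero-variance features get SD 1), then a soft-margin linear
SVM (libsvm via scikit-learn, cost 1) is fitted; the stored statistics
transform test vectors identically. Tests cross-check predictions
against an independent dual-QP solver.

## Evaluation

**Cross-validation.** Stratified folds deal each class's shuffled
trials round-robin across k folds (per-class counts differ by ≤ 1);
10 repetitions × 10 folds by default. Everything data-dependent —
standardization, Ledoit–Wolf selection, bootstrap draws — happens
inside the training split of each fold; a leakage test corrupts
held-out trials and asserts fold-mate predictions are unchanged.
Stochastic classifiers are seeded per (run seed, repetition, fold), so
runs are bit-reproducible, and all compared classifiers share one fold
assignment (paired design).

**Ensemble-size selection.** Two modes exist because selecting
N_learn on the evaluation folds is optimistically biased: the default
nested mode re-selects inside each training fold via an inner 5-fold
CV; `outer_selection` (CLI `--outer-selection`) selects the argmax of mean outer
CV accuracy over the grid, the protocol typical of offline
grand-average analyses. Ties always go to the smaller value. Reports
label the mode.

**Bitrate.** Wolpaw ITR per minute with 0·log₂0 := 0 at the accuracy
endpoints. T defaults to the 10-s task period ("time on task"); a
config option (`count_break_in_trial`) uses task + mean break for
stricter online accounting.

**Chance level.** The smallest k with an exact binomial tail
P[X ≥ k] < α at p = 1/n_classes, returned as k/n_trials. Note the
threshold is non-increasing in n_trials only up to the one-count
granularity 1/n — discreteness causes sub-1/n upward steps.

**Statistics.** Anderson–Darling composite normality: A² with
estimated mean/variance (SD divisor n − 1), small-sample correction
A²·(1 + 0.75/n + 2.25/n²), and the standard piecewise-exponential
p-value approximation; validated against frozen R `nortest::ad.test`
values and calibrated to a 4–6% type-I rate at α = 0.05 (n = 29,
10,000 replicates). The paired t-test refuses zero-variance
differences rather than reporting p = 0. Multiple comparisons use
Benjamini–Hochberg FDR exclusively (the source protocol's correction).
If normality is rejected the report records the screen and still runs
the t-test; a Wilcoxon signed-rank fallback is available but off by
default. Paired units are per-repetition mean accuracies (10 values
per method within one session) — a within-session analogue of
per-participant pairing, which a single synthetic subject cannot
provide.

## Synthetic data

**Sessions.** Block design with randomized class order: 10-s tasks,
breaks uniform in [15, 17] s, 30 trials per class, 9 channels at
12.5 Hz by default (all configurable to the 10.4–13.3 Hz /
16-channel variants). Per trial the neural boxcar is convolved with a
double-gamma HRF (gamma shapes 6 and 16, scale peak/5, peak 6 s,
undershoot ratio 0.2), normalized so an isolated trial peaks at
exactly the configured amplitude; ΔHbR is a scaled delayed mirror of
ΔHbO (ratio −0.3, delay 1 s) — a stylized convention. Class effect
maps default to distinct spatial patterns (channel c responds fully
to class k iff c mod K = k, at 15% otherwise) with peak amplitude
0.15 µmol/L, which under the default noise puts default-session CV
accuracy around 0.90 — the upper range of binary mental-task BCIs.
Noise per channel: cardiac 1.2 Hz and respiratory 0.25 Hz sinusoids
(amplitudes 0.4 µmol/L), Mayer 0.1 Hz (0.3), a random-walk drift
scaled to SD 0.5, and white noise SD 0.2, all with seeded independent
phases; ΔHbR noise is scaled to 40%.

What this emulates: the timing structure, spectral nuisance content
and amplitude regime of block-design prefrontal recordings. What it
does not: real noise covariance across channels, motion artifacts,
serial dependence of behaviour, or between-participant variability —
so passing benchmarks show the pipeline's statistical machinery works
under its stated assumptions, not that specific published accuracies
transfer.

**Gaussian feature harness.** Per-class multivariate normals with one
shared covariance. The "weak separation" condition used by the
benchmark suite is d = 36 (9 channels × 2 chromophores × 2 windows),
30 trials per class, identity covariance, equal per-dimension mean
offset 0.25 — Mahalanobis separation 1.5, Bayes accuracy ≈ 0.77. In
this regime plain LDA loses several accuracy points to covariance
noise, which is exactly where bagging and shrinkage help; the
benchmarks assert the directional claims (bagged ≥ plain LDA on
average; accuracy vs N_learn rises then plateaus across
{1, 5, 10, 25, 50}; null data stay at chance with a calibrated
false-flag rate).

## Problem sizes and determinism

The Monte-Carlo benchmarks use 20 replicate datasets for the
advantage/size-curve estimates and 30–100 for null calibration, each
with full 10×10 CV — sizes at which the reported means are stable to
about a percentage point while a complete run stays in the minutes
range on one CPU. Every random draw flows from an explicit integer
seed (numpy `default_rng`); there is no wall-clock seeding anywhere,
and repeated runs are byte-identical apart from a manifest timestamp.

## Known limitations

- The MBLL default coefficients are conventions; unit-sensitive
  results require instrument values.
- The literal identity shrinkage target makes γ scale-dependent
  (accepted; features share µmol/L).
- Multiclass vote aggregation over multiclass weak learners is one of
  several defensible conventions (one-vs-one voting inside each weak
  learner being the alternative).
- `compare_report` aborts on zero-variance accuracy differences
  (e.g. two methods both at ceiling) by design, surfacing the
  degenerate pairing instead of fabricating a p-value.
- Single-session scope: no multi-subject modeling, no online
  operation.
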