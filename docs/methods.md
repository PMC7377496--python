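# Methods

This note documents the models, defaults and design choices behind
`gaitpd`, and what the simulation-based validation does and does not show.

## The signal model behind the synthetic cohorts

The study design being emulated is a supervised ~20-step hallway walk with
a smartphone fixed at the waist: the subject stands still, walks ~20 steps,
and stands still again, while accelerometer and gyroscope sample at a
nominal 100 Hz with slightly asynchronous timestamps.

Each simulated recording is built in continuous time and sampled on a
100 Hz grid perturbed by uniform ±2 ms jitter (so the interpolation stage
does real work). Its components:

* **Step timing.** Step intervals are Gaussian with mean 1/cadence and a
  configurable coefficient of variation (CV), clipped to [0.4, 1.8] × the
  mean step time. Heel strikes are the cumulative sums; each toe-off sits
  ~35% into its step cycle (±8% jitter). A terminal foot contact — the stop
  — follows the last step: it closes the last cycle's *B* interval but
  begins no new step, exactly as a subject halting does.
* **Vertical acceleration (x, up-positive).** A +1 g gravity baseline;
  a sharp negative Gaussian pulse (σ = 20 ms) at each heel strike; a
  broader positive pulse (σ = 35 ms) at each toe-off; first and second
  step-frequency harmonics (12% and 6% of heel-strike amplitude) gated by a
  smooth activity window. Left/right amplitude asymmetry alternates by
  step; amplitudes get 6% step-to-step modulation.
* **Other channels.** Mediolateral sway at stride frequency, anteroposterior
  propulsion at step frequency, gyroscope oscillations at stride/step
  frequencies scaled by `gyro_scale_dps`, attenuated copies of the impact
  transients, and white sensor noise (accelerometer SD `noise_sd_g`,
  gyroscope 25× that in deg/s).
* **Idle periods.** 1–3 s (uniform) of standing at each end: gravity
  baseline plus sensor noise only.

Ground truth — heel-strike times, toe-off times, and the walking interval
between the half-amplitude points of the activity gate — is stored with the
recording, so segmentation fidelity is measured against exact event times,
not against another detector.

**Group profiles.** The clinical literature consistently reports slower,
more variable, lower-impact gait in PD; magnitudes for a given cohort are
not standardized, so the defaults here were fixed once as plausible,
deliberately well-separated values and are not estimates of any patient
population:

| parameter | control | PD |
| --- | --- | --- |
| cadence (steps/s) | 1.85 | 1.55 |
| step-time CV | 0.025 | 0.09 |
| heel-strike amplitude (g) | 1.1 | 0.70 |
| toe-off amplitude (g) | 0.75 | 0.48 |
| amplitude asymmetry | 1.05 | 1.18 |
| gyro scale (deg/s) | 45 | 30 |

Between-subject variability multiplies each parameter by 1 + 0.05·N(0, 1)
(clipped at ±2.5 SD). Cohorts are balanced (29 + 29 by default, two
recordings of 19–20 steps per subject with a 15% chance a second recording
is missing, keeping 19–40 steps per subject).

The generator deliberately omits: tremor and freezing episodes, turning,
non-walking activities, orientation drift, and any biomechanically derived
waveform shape. Passing tests therefore show that the pipeline recovers
what this signal model encodes — they do not certify performance on
clinical recordings.

## Preprocessing

* **Synchronization** trims both sensor streams to the common time span
  [max(starts), min(ends)] and interpolates the gyroscope onto the
  accelerometer's surviving timestamps.
* **Resampling** is linear interpolation onto a uniform grid (default
  100 Hz) covering the original span, never extrapolating. Linear is ample
  at 5× oversampling relative to the 20 Hz band; cubic is available via
  `kind=`.
* **Filtering** is a 4th-order low-pass Butterworth at 20 Hz (meaningful
  human movement is below 20 Hz). The default application is zero-phase
  (`filtfilt`, odd reflective padding of 3 × order), because downstream
  heel-strike/toe-off timing must not be phase-shifted; this squares the
  magnitude response, which the validation accounts for. A `causal=True`
  single-pass mode exists for streaming-like use.

## Segmentation

* **Walking-span detection.** The RMS-combined stationary-wavelet (db4)
  detail envelope of the vertical acceleration at levels 3–5 (≈1.5–12.5 Hz
  at 100 Hz sampling — step harmonics plus impact transients) is smoothed
  over 0.2 s and thresholded at max(0.12 g, 0.25 × envelope max); the
  absolute floor makes a standing-only recording raise "no walking
  detected" rather than return noise. Supra-threshold runs separated by
  < 0.7 s merge; the longest run wins. Because wavelet support smears the
  envelope by a few hundred ms, span edges are refined with a 0.11 s
  running SD of the raw signal (threshold max(4 × noise floor, 10% of the
  walking level)), which hugs the true movement onset/offset to within
  ~0.1 s.
* **Event detection.** Troughs below −0.5 SD and peaks above +0.5 SD of the
  demeaned in-span signal (relative thresholds adapt across subjects;
  configurable multipliers), with a 0.3 s inter-trough refractory period
  (physiological cadence ceiling ~3 steps/s). Same-sign neighbours collapse
  to the more extreme; cycles are trough→peak→next-trough triples yielding
  *Aᵢ* and *Bᵢ*.
* **Windowing.** *W* = round(fs·(mean *A* + mean *B*)) per recording
  (a cohort-global *W* can be imposed via `window_length=`); windows start
  at the heel strike; steps overrunning the recording end are dropped and
  logged; *W* < 10 samples is an error.

## Features

The default registry has exactly 201 entries: 24 statistics × 6 channels
(144) + 15 channel-pair Pearson correlations + 21 statistics × 2 magnitude
channels (42). The 24 per-channel statistics: mean, median, SD, variance
(both ddof = 1), min, max, range, RMS, IQR (linear-interpolation
percentiles), median absolute deviation, skewness and excess kurtosis
(biased moment estimators, 0 on constant input), signal energy, mean
absolute value, zero-crossing count, mean-crossing count, first/last-sample
difference, lag-1 autocorrelation, dominant frequency, dominant-frequency
power fraction, spectral entropy (nats), spectral centroid, and relative
band powers 0.5–3 Hz and 3–8 Hz. Spectral quantities come from the
one-sided periodogram with the DC bin excluded; band powers are fractions
of non-DC power. The magnitude channels (acc-norm includes gravity) drop
the two crossing counts and the first/last difference, which are degenerate
or edge-dominated on non-negative signals. Correlations of zero-variance
pairs are defined as 0, keeping the matrix finite. No normalization happens
at extraction; standardization is fit per training fold inside
classification.

## Selection

* **mRMR** discretizes each feature by equal-frequency binning into 8 bins
  (plug-in MI in nats) and greedily maximizes relevance − mean redundancy
  (MID; MIQ switchable). Ties break toward the lower feature index, making
  the ranking deterministic with the greedy-prefix property.
* **SFS/SBS** optimize the misclassification rate of a 10-fold
  subject-grouped CV (groups = subjects, so the wrapper criterion has no
  identity leakage). Both stop at the first round with no strictly
  improving move; SBS additionally honours an evaluation budget
  (`max_evals`) since its cost on 201 features is prohibitive.
* **RF importance** fits one forest on all features and keeps the top 20 by
  impurity importance.
* **Leakage modes.** The default reproduces the protocol of selecting once
  on all steps and then running LOSO; `nested_selection=True` re-selects
  inside every training fold. The difference matters: under a zero-effect
  simulation the select-once mode is optimistically biased (features
  cherry-picked on all subjects' steps), while the nested mode stays at
  chance — which is why the null-control analysis uses it.

## Classification

Nine classifiers, all wrapped as scaler + model with the scaler fit on the
training fold only: decision tree; an RBF-kernel learner implemented as
random Fourier features (300 components) + logistic regression; LDA;
AdaBoost over 100 depth-1 stumps; kNN with k = 49 (odd so binary votes
cannot tie, ≈ √n for ~2000 training steps); logistic regression; Gaussian
naive Bayes; linear-kernel SVM (C = 1); and a random forest of 100 trees
with √p features per split. The repeated-forest protocol runs an odd
number (11) of independently seeded forests and majority-votes each test
step, eliminating both vote ties and single-seed variability. Class priors
follow training-fold frequencies (cohorts are balanced by design).

## Evaluation and statistics

* **LOSO**: one fold per subject (sorted by id); fold construction uses
  metadata only.
* **Metrics** are pooled over folds (micro-average): accuracy = correct
  steps / all steps; sensitivity over true-PD items; specificity over
  true-control items. Subject calls: PD iff the PD-step fraction exceeds
  0.5; an exact tie defaults to PD (screening favours sensitivity;
  configurable). Misclassification rate = 1 − subject accuracy.
* **Cochran's Q** is computed from the standard formula on the
  items × classifiers correctness matrix (chi-square, k − 1 df); degenerate
  matrices give Q = 0, p = 1. For k = 2 it reduces to the uncorrected
  McNemar statistic (asserted numerically in tests; statsmodels serves as
  an independent oracle).
* **Post-hoc** pairwise comparison uses rank-based Dunn z-tests with tie
  correction and Bonferroni adjustment over the C(k, 2) pairs (α = 0.01);
  pairwise McNemar is available as an alternative backend. Neither backend
  is claimed to reproduce any specific published p-value — the combination
  of Cochran's Q with Dunn's test is unusual and underdetermined.

## Validation scales and numerical choices

The acceptance checks run at sizes chosen as a deliberate compromise
between statistical power and a desk-scale run: 50 recordings × 20 steps
for segmentation fidelity (heel-strike recall/precision within ±50 ms);
58-subject single-recording cohorts (~1 150 steps) for the end-to-end
discrimination and null analyses, with mRMR-15 features and the full
nine-classifier bank. Because steps within a subject are strongly
correlated, the effective sample size of any cohort-level accuracy is the
number of subjects; the null check therefore uses the exact central 95%
binomial interval on 58 trials. Feature-extraction equivalence is checked
against a pure-Python, naive-DFT reimplementation at 1e-9 relative
tolerance; selection is checked against brute-force greedy oracles on small
matrices.

All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning (derived seeds kept below 2³¹); reruns
are bit-identical.

## Known limitations

* The 201-feature registry is a documented reconstruction of a standard
  human-activity-recognition inventory constrained to the stated category
  structure; any exact published list can be dropped in via the serializable
  registry.
* The "Gaussian kernel" and "Ensemble" members are reasonable modern
  equivalents of loosely specified toolbox learners, not re-implementations
  of any particular one.
* Synthetic validation bounds what can be claimed: the pipeline's clinical
  accuracy on real smartphone recordings is untested here by construction.
* Left/right foot attribution, stride-to-stride (multi-step) features,
  UPDRS-subgroup analyses and free-living walking detection are out of
  scope.
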