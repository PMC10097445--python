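# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and what passing tests do and do not establish.

## Signal model for seated chest movements

Streams are generated in the device frame of a phone worn flat at the center
of the clavicle on an upright sitter: **z** carries gravity (9.81 m/s²),
**x** is lateral, **y** anterior–posterior.  Each activity is a simple
kinematic signature plus white Gaussian sensor noise (default sd
0.3 m/s²):

| class      | structure                                   | default freq | default amp (m/s²) |
|------------|---------------------------------------------|--------------|--------------------|
| still      | gravity + noise only                        | —            | —                  |
| swing      | lateral (x) sinusoid                        | 0.6 Hz       | 2.0                |
| rock       | anterior–posterior (y) sinusoid             | 0.6 Hz       | 2.0                |
| rotate     | quadrature sinusoids on x and y             | 0.5 Hz       | 1.5 each           |
| walk       | vertical bounce + slower horizontal sway    | 2.0 Hz step  | 3.0 z, 1.0 x, 0.5 y|
| stand_sit  | alternating-sign Gaussian pulses on z       | every 2.5 s  | height 4.0, FWHM 0.5 s |

Frequencies sit well below the 5 Hz Nyquist limit of a 10 Hz recording and
inside the 2–5 s time span typical of everyday movements; amplitudes are
plausible orders of magnitude for torso motion.  The generator validates the
Nyquist constraint and refuses non-positive durations/rates.

Per-subject variability is multiplicative log-normal jitter on amplitudes
(cv 0.15) and frequencies (cv 0.08), drawn from a stream seeded by
`(seed, crc32(subject_id))`.  This is what makes leave-one-subject-out
evaluation a genuine generalization test: each held-out subject moves at
slightly different amplitudes and tempi than anyone in the training set.

**What this emulates and what it does not.**  The generator reproduces the
*spectral layout* of the six activities — which axes and frequency bands
carry energy — and inter-subject variation in scale and tempo.  It does not
model gait biomechanics, posture drift, device re-orientation, harmonics, or
heavy-tailed sensor noise.  High synthetic LOSO accuracy therefore shows the
pipeline is correct and that spectrally distinct movements are learnable
across subjects; it does not certify any particular accuracy on real
recordings.

## Preprocessing

Working rate 10 Hz; windows of 20 samples (2 s) with 50 % overlap (hop 10),
half-open `[start, start+width)` with 0-based indices, giving exactly
`floor((N−20)/10)+1` windows.  Streams recorded faster are brought to 10 Hz
by linear interpolation onto the uniform grid (upsampling is refused).
Window labels are the majority per-sample label, ties resolved to the
window's first sample.  Gravity correction subtracts each axis column's mean;
features are magnitudes of the one-sided unnormalized DFT (11 bins × 3 axes,
0.5 Hz bins), so Parseval's identity reads `sum(x²) = sum(|X|²)/width` over
the two-sided spectrum and the DC bin vanishes after correction.  No taper
is applied before the DFT — the pipeline is mean subtraction and Fourier
transform only.  Frequency-domain sequences are the classifier input; phase
is discarded.

## Classifier

Architecture: sequence input (3 channels) → LSTM(20, full sequence) →
dropout p = 0.1 → LSTM(30, last output) → dense(6) → softmax.  The "20 + 30
hidden units with a dropout layer" are realized as two stacked recurrent
layers with the single dropout between them; classification uses the second
layer's final time-step state since each window carries one label.  Training:
cross-entropy, SGD with momentum 0.9 (the conventional default for that
solver), learning rate 0.001, mini-batch 30, 300 epochs, no early stopping.
Inputs are standardized per (bin, axis) with training-set statistics stored
in the model, which keeps the fixed learning rate usable across amplitude
scales.

The network is implemented directly in numpy (single precision) with
hand-written backpropagation through time, verified against central finite
differences to ~1e-6 relative error.  Gate sigmoids use
σ(x) = (1 + tanh(x/2))/2 for stability; forget-gate biases start at 1,
other weights Glorot-uniform from a seeded generator.  Everything —
initialization, shuffling, dropout masks, per-fold seeds — derives from one
config seed, so a full LOSO run is bit-reproducible.  The recorded history
is per-epoch mean mini-batch loss and mini-batch accuracy as observed during
training (dropout active).

LOSO cross-validation trains one fold per subject on the remaining subjects
and reports the arithmetic mean of fold accuracies.  Confusion matrices are
oriented rows = predicted, columns = actual.  Prediction ties break toward
the lowest canonical class index; the canonical order is
(walk, stand_sit, rotate, swing, rock, still) everywhere.

Problem sizes: the validation runs use five synthetic subjects with 60 s per
activity (359 windows each, ≈1 400 training windows per fold), which the
test suite and acceptance script complete in a few minutes on one CPU while
leaving enough data per fold for stable accuracy estimates.

## Long-recording labeling

`label_stream` runs resample → slice → gravity-correct → spectra → predict
and tallies per-class window counts; counts always sum to the window total.
Raw counts are reported by default — no temporal smoothing — matching how
movement counts enter the downstream statistics; an optional majority-vote
smoother over the label track is available but off by default.

## Navon-task statistics

*Shift tagging.*  In the mixed phase, trial *i* (i ≥ 2) is a shift trial iff
its required level (global/local) differs from trial *i−1*'s.  The first
mixed trial has no predecessor: it is tagged `undefined` and belongs to
neither set.  Without that exclusion a 40-trial block could not split into
half shift / half nonshift after conditioning on transitions.

*Condition summaries.*  Reaction times are averaged over accurate trials in
every condition; shift accuracy is correct-shift / all-shift.  Subjects with
no accurate trial in a condition are recorded as missing and logged, never
imputed.  The subject-level "reaction time" used by the mediation model is
the same accurate-shift-trial mean.

*Repeated-measures ANOVA.*  Standard one-way within-subject decomposition;
Greenhouse–Geisser ε from the double-centered condition covariance, clipped
to [1/(k−1), 1]; p evaluated at fractional dfs ε(k−1) and ε(k−1)(n−1).  At
k = 2, ε = 1 and F equals the squared paired-t statistic exactly.  Effect
size is partial η² = SS_effect/(SS_effect+SS_error), the conventional report
for corrected within-subject designs.  Missing cells are rejected.  The
implementation agrees with pingouin's GG-corrected ANOVA to machine
precision on random data (test-suite cross-check).

*Pairwise comparisons.*  All k(k−1)/2 contrasts share the pooled error term:
SE = √(2·MS_error/n) with df = (n−1)(k−1); t is exactly diff/SE.  Both
Bonferroni (× number of pairs, capped at 1) and Holm step-down p-values are
reported; Holm is validated against statsmodels.

*Correlations.*  Pearson r with two-sided p from
t = r√((n−2)/(1−r²)), pairwise deletion for missing values (the stress
index can be missing), pairs with < 3 complete observations or zero
variance reported as missing.

*Mediation.*  One path model with all three movement predictors (swinging,
rotating, sitting) entering jointly: a mediator equation
RT ~ movements and outcome equations outcome ~ RT + movements for accuracy
and stress.  Equations are fit by OLS — identical to ML point estimates
under normal errors.  Indirect(X→Y) = a_X·b_Y; total = direct + indirect
exactly (an algebraic identity of the linear path model, asserted to 1e-10).
Point SEs are delta-method: Sobel for the indirect effect, and for the total
effect Var(c′) + b²Var(a) + a²Var(b) + 2a·Cov(c′, b) using the outcome
equation's coefficient covariance (a is independent, coming from the other
equation).  Confidence intervals are bias-corrected percentile intervals
over case-resampled bootstrap replicates (default 2000, seeded); resamples
with singular or ill-conditioned designs (condition number > 1e12) are
skipped and the achieved count reported rather than guessing a correction.
Rows missing stress are excluded from the stress equations only; accuracy
equations keep them.  Standardized estimates come from refitting on z-scored
variables.

## Experiment-2 synthetic cohort

Movement counts are independent normal draws at the study-scale descriptive
means/SDs (e.g. swinging 44.5 ± 21.4, sitting 1082.6 ± 332.7 windows per 30
min), clipped at zero and rounded to integers — clipping (rather than
resampling) keeps the sample mean within ~1 count of the target even for
variables whose mean sits ~2 sd above zero.  Reaction time, accuracy and
stress follow the linear path model RT = α + Σa_X·X + ε,
Y = α' + b·RT + Σc′_X·X + ε', with intercepts chosen so the marginal means
match their targets and residual sds defaulting to values that preserve the
marginal spreads given the planted coefficients.  Accuracy is clamped to
[0, 1]; the default cohort therefore has a mildly attenuated RT→accuracy
slope near the ceiling, which is why planted-effect *recovery* tests place
the accuracy mean at 0.5 where the clamp is inactive and the generating
model is exactly linear.  Stress goes missing completely at random with
probability 2/28 by default.  Default planted effects: swinging lowers RT
(−9.39 ms per window, giving r ≈ −0.39 at the default scales) and RT mildly
lowers accuracy (−3e−5 per ms); other paths are zero.

Trial tables contain, per subject, 20 global, 20 local and 40 mixed trials.
The mixed global/local sequence is built with the number of switch and stay
transitions balanced to within one and switch positions placed at random —
balance by construction, matching a task design of half shift / half
nonshift trials.  Reaction times are lognormal (positive, right-skewed) with
moments matched to the per-condition mean/sd; the untagged first mixed trial
draws from the nonshift condition.  Correctness is Bernoulli per condition
(defaults ≈ 0.97).  The per-condition sds are applied at the trial level, so
between-subject spread of condition means is tighter than the target sds by
≈ 1/√(trials); the generator targets the condition means, not the
between-subject variance structure, and the ANOVA consequently rejects very
decisively on default cohorts.

## Known limitations

* The motion models are stand-ins: no published signal amplitudes or axis
  conventions exist for the original recordings, so their realism cannot be
  validated against recorded data — only the pipeline's correctness and the
  learnability of spectrally distinct classes.
* Per-participant accuracies on real recordings are not reproducible without
  the original data; only the printed-mean arithmetic and synthetic-data
  properties are testable, and the acceptance script makes that distinction
  explicit.
* The mediation model is linear with case-resampling; it does not model
  measurement error in movement counts or non-linear RT–accuracy links.
* Gyroscope channels are out of scope (they degraded classification and
  were discarded in the motivating design), as are real-time inference and
  device drivers.
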