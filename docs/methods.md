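# Methods

This note documents the models, defaults and design choices behind
`myofitts`, and what its synthetic experiments do and do not demonstrate.

## Synthetic EMG model

Surface EMG is modelled as amplitude-modulated coloured Gaussian noise.
White noise is shaped in the frequency domain to the parametric sEMG
power spectral density

    S(f) = f² · f_h⁴ / ((f² + f_l²)(f² + f_h²)²),

band-pass filtered to the acquisition band (4th-order zero-phase
Butterworth, 10–500 Hz) and normalised to unit RMS. With the default
corners f_l = 60 Hz, f_h = 120 Hz the realised spectrum peaks at roughly
80–100 Hz and carries well under 1 % of its power above 500 Hz, matching
typical forearm recordings. The acquisition chain defaults — 2048 Hz
sampling, gain 1500, four bipolar channels — mirror a standard laboratory
amplifier setup.

A session is a deterministic function of (protocol, pattern, acquisition,
electrode type, seed). Per repetition the timeline is a 3 s countdown,
6 s gesture, 6 s rest; the offline protocol runs nine gestures × four
repetitions, the online protocol five classes × three repetitions. During
a gesture, channel `c` receives coloured noise scaled by
`activation[c, g] · snr_scale`, with 200 ms raised-cosine on/off ramps
(which also motivate trimming 1 s per event end downstream); baseline
instrumentation noise (default RMS 0.1 signal units, a free parameter
since resting amplitude is rarely characterised) is present throughout,
so gesture-span SNR is ≈ 20 dB at unit activation. The built-in 4×9
activation template uses extensor-dominant patterns for extension/open,
flexor-dominant for flexion/close and mixed overlapping patterns for
grips and rotations, making classes separable but not orthogonal; the
rest column is zero. Fabric electrodes are gel electrodes with
`snr_scale × 0.8` (reduced SNR); no bandwidth difference is modelled.

Not modelled: motor-unit firing statistics, channel crosstalk,
electrode-skin impedance, ADC quantisation, fatigue or session-to-session
drift. Consequently, passing tests show the *pipeline* recovers structure
that is present by construction — they say nothing about inter-subject
variability or non-stationarity in real recordings, and the
near-ceiling synthetic accuracies should not be read as predicted human
performance.

## Feature pipeline

Events are trimmed 1 s per end (6 s → 4 s), mean-subtracted per channel
*per event*, and segmented with a 200 ms window and 50 ms overlap between
consecutive segments — i.e. a 150 ms stride, the literal reading of
"overlap"; a 50 ms *stride* convention is common in the literature and
available via `WindowingConfig`. At 2048 Hz neither length is integer, so
both are rounded to the nearest sample: 410-sample windows, 307-sample
stride, giving 26 windows per trimmed event and closed-form window count
`floor((L − w)/s) + 1`.

The six features use the standard definitions (see README). Deadband
thresholds for ZC/SSC/WAMP default to 0: after mean subtraction this is
workable at simulation amplitudes, though it makes WAMP constant
(window length − 1) and hence uninformative until a positive threshold is
set — the PCA step tolerates such zero-variance columns by leaving them
unscaled. SSC uses the strict-inequality extremum product with an
either-side deadband, the most common published convention; the test
oracle implements the same definitions independently as naive loops.

## Classifier

Features are centred and scaled to unit variance before the
eigendecomposition (counts and amplitudes differ by orders of magnitude;
`standardize=False` is available), and the minimal number of components
whose cumulative explained variance reaches 0.95 is retained. Component
signs are fixed (largest-magnitude loading positive) for determinism.

The network is 18 tansig hidden units and a softmax output layer trained
by Levenberg–Marquardt on the sum-squared error against one-hot targets —
the standard pairing for this trainer, cross-entropy being out of scope.
The residual Jacobian is computed analytically by backpropagation; each
epoch solves `(JᵀJ + μI)δ = −Jᵀr`, accepting the step (and multiplying μ
by 0.1) only if training error decreases, otherwise raising μ ×10 and
re-solving. Schedule defaults (μ₀ = 1e−3, ×10/×0.1, cap 1e10, patience 6,
epoch cap 1000) follow the de-facto standard LM trainer. Reaching the μ
cap without an accepted step is treated as normal convergence (no descent
direction remains) and returns the best-validation weights; a
`ConvergenceError` carrying the training log is reserved for non-finite
errors. Weights initialise from a seeded uniform [−0.5, 0.5] draw scaled
by 1/√fan-in, so training is fully reproducible. Early stopping returns
the weights of the best validation epoch after `patience` consecutive
non-improving epochs.

The 5-class online model reuses the same 18-unit architecture as the
9-class offline model.

## Cross-validation

Ten stratified test folds partition the windows; per fold, a seeded
stratified 1/9 of the remaining rows forms the validation set, yielding
the 80/10/10 overall split (how validation rows are chosen is otherwise
unspecified, so this is a documented choice). Each fold trains a fresh
seeded network (seed offset by fold index). By default PCA is fitted once
on the full table before the folds are formed — matching the usual
prepare-then-split ordering of this pipeline, at the cost of letting test
rows influence the projection; `pca_per_fold=True` gives the leakage-free
variant. Windows from one repetition may land in different folds
(window-level CV); `grouped=True` keeps repetitions together for
leakage-averse analyses. Reported accuracy is mean ± sample sd over fold
accuracies; the pooled confusion matrix yields per-class precision/recall
with NaN marking zero-denominator entries.

## Fitts'-law game

Targets sit at Euclidean distance D from the origin at a seeded uniform
angle (the task is genuinely two-axis; `axis_aligned` mode places them on
a random half-axis for analysis). The cursor clamps at the ±110 grid
boundary. Gesture→direction defaults: extension +x, flexion −x, open +y,
close −y (configurable — any assignment is equivalent under symmetry).

Dwell and timing: a 200 ms tick advances the cursor one step; a tick
counts toward the 1 s dwell only when the cursor is inside the target
both before and after the move, so the arrival tick starts — but does not
count toward — the hold. Completion time is tick count × 0.2 s,
*inclusive* of the dwell second; for a perfect user on an axis-aligned
target it equals `ceil((D − W/2)/step) × 0.2 + 1.0` exactly. Throughput
averages ID/C over successful trials only (failed trials have no C);
completion rate counts successes over all 24 targets. Both conventions on
the dwell question are recomputable from the per-tick trace the game
logs.

The intent-level simulated user moves greedily along the axis with the
larger remaining centre distance and rests inside the target, with each
intended gesture passed through a per-tick confusion matrix; the
closed-loop user instead synthesises one 410-sample frame per tick from
the activation pattern and classifies it with the trained network. The
intent model isolates the usability–accuracy link; the closed-loop model
exercises the whole chain.

## Study orchestration

`run_offline_study` / `run_online_study` reproduce the full structure:
three subjects (template activation with seeded ±20 % multiplicative
jitter per subject — real per-subject signal characterisation being
unavailable, this is a pragmatic individuality model), both electrode
types in counterbalanced order (recorded for structural fidelity; order
cannot affect a drift-free simulation), subject-specific and pooled
cross-validations, and three 24-target games per subject × electrode.
Every child seed derives from the master seed plus a string path
(`derive_seed`), so identical master seeds give byte-identical report
JSON and any sub-computation can be reproduced in isolation.

## Problem sizes and tolerances

Tests run the full single-session pipelines (936-window offline tables)
but cap LM training at 8–30 epochs where many networks are trained (CV
and study tests) — accuracy on the synthetic task saturates within ~20
epochs, and the study-level tests use one subject with two repetitions to
keep the suite brisk. Numerical assertions use exact equality for counts
and permutations, 1e−9..1e−12 absolute tolerance for algebraic
identities, ±20 % for RMS recovery against the generator's nominal
baseline, and a 3-sd binomial band around 1/9 for the permuted-label
chance control.

## Known limitations

- The generator's class separability is set by the activation template;
  accuracies on synthetic data are near ceiling and not comparable to
  human-subject results.
- Default (prepare-then-split) PCA leaks test information into the
  projection; use `pca_per_fold=True` for strict generalisation claims.
- LM forms the full `JᵀJ`; fine for a few hundred parameters, unsuitable
  for much larger networks.
- WAMP at the default zero threshold is constant and carries no
  information.
- The closed-loop user synthesises stationary frames per tick; it does
  not model gesture transitions within a frame.
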