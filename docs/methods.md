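# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite shows.

## Signal conditioning

Offline conditioning assumes a continuous recording with a cue schedule:

- **Filtering.** 10–500 Hz band-pass (Butterworth, order 4) and a 50 Hz
  band-stop (Butterworth, order 2, ±2 Hz half-bandwidth). Both are applied
  forward–backward (`sosfiltfilt`), which gives zero phase at the cost of
  doubling the effective order; for offline analysis the phase linearity is
  worth more than the exact printed order. Pre-conditioned data styles can
  skip this step (`filter_cfg=None`).
- **Segmentation.** One trial per movement-phase cue interval; the preceding
  rest interval is kept as the trial's baseline reference. A movement
  without a preceding rest falls back to the pooled rest signal with a
  warning.
- **Onset detection.** Envelope = cross-channel mean of the
  moving-average-smoothed rectified signal (default smoothing 100 ms).
  Threshold = baseline-envelope mean + 3 SD; the active interval runs from
  the first to the last exceedance sustained ≥ 50 ms. The three constants
  are conventional defaults, exposed in `OnsetConfig`; a trial whose
  envelope never exceeds the threshold is dropped and logged. The 100 ms
  transient trim is applied to the onset-detected interval (floor for the
  ms→samples conversion, so never more than 100 ms is consumed).
- **Windowing.** 512-sample windows, 128-sample stride
  (250 ms / 62.5 ms / 384-sample overlap at 2048 Hz);
  `n_windows = floor((L − W)/S) + 1`. Windows never cross trial boundaries.
- **Splits.** Whole repetitions go to train or test. The first-3-of-5
  policy takes the first three repetitions per (class, orientation) in
  acquisition order — a deterministic choice where any 3-of-5 assignment
  would be defensible. The 1/3/4/6-vs-2/5 policy matches the common
  six-repetition convention.

## Features and classical baselines

Per channel and window: MAV, IEMG, RMS, WL, ZC, SSC, Hjorth activity
(variance), mobility and complexity (first differences, unit spacing),
bias-adjusted skewness, SampEn, and cepstral coefficients CC1–4.

- ZC/SSC use an amplitude gate ε; default ε = 0.01·SD(window) (configurable,
  0 for the textbook counts). A zero-variance window yields the 0 sentinel
  with a warning wherever a feature is undefined.
- SampEn(m=2, r=0.2·SD): Chebyshev distance, self-matches excluded, both
  template lengths restricted to the first n−m starting points so the two
  counts are comparable. Verified against an O(n²) explicit-counting oracle.
- CC from an AR(4) fit: Levinson–Durbin on the biased autocorrelation,
  prediction-error convention A(z) = 1 + Σ a_k z^(−k), then
  c₁ = −a₁, c_n = −a_n − Σ_{k<n} (1−k/n)·a_k·c_{n−k}. The CB set exports
  CC1 only; the Full set CC1–4 from the same order-4 fit.
- Scaling: per-column z-scoring with train statistics computed after
  winsorizing train values at ±3 SD. Winsorization (rather than row
  deletion) keeps rows aligned with labels; clipped counts are logged.
- Baselines: KNN (k=40, Euclidean), SVM (linear, C=1), MLP (one hidden
  layer of 300 tanh units, learning rate 1e-4), LDA — hyperparameters taken
  as given, no search.

## The decoders

Both convolutional variants share one topology: 3 × (conv → BN → RReLU →
max-pool(1,4) over time → dropout 0.3) → flatten → dense-300 block →
dense-50 block → dense n_classes. `cnet2d` kernels span 3 adjacent
electrodes ('valid' on the channel axis, 'same' on time: channel extent
10→8→6→4); `cnet1d` kernels are (1,k). RReLU slope ~ U[1/8, 1/3] in
training, its midpoint at evaluation. The number of conv filters per block
is a free choice (default 32/64/64; the desk-scale harness uses 4/8/8) —
every architecture-derived parameter count of interest concerns the head
only and is independent of it.

Training: Adam, cross-entropy, batch 128 (32 at desk scale), seeded 20 %
random validation hold-out, weights restored from the minimum-validation-
loss epoch, optional early-stopping patience. Decaying schedules are
realized as per-epoch exponential decay from the initial to the final rate.
Seeds control initialization, the validation split, shuffling, dropout and
RReLU draws; two runs with the same seed are bit-identical.

The layer engine (`myodecode.nn`) is a compact numpy implementation with
explicit per-layer backward passes — conv via im2col + GEMM, standard BN
backprop, inverted dropout — validated by central-difference gradient checks
and a `scipy.signal.correlate2d` oracle. Batch-norm uses momentum 0.1 and
ε = 1e-5. Argmax tie-breaks resolve to the lowest class index everywhere.

## Subject transfer (PFCnet)

The target-trained and source-trained conv stacks (through flatten) are
copied, their conv weights frozen, and their flattened outputs concatenated
under a freshly initialized 300/50/n head. Batch-norm scale/shift in the
frozen extractors remain trainable and their running statistics keep
updating, so the extractors re-normalize to the target's data — the one
part of a "frozen" extractor that must stay plastic for cross-subject use.
"Feature layer" is interpreted as the flattened conv-stack output: the
classifier part that gets discarded is the dense blocks. The head mirrors
the base head dimensions. The final stage re-draws its validation split
(seeded).

## Task transfer

- **Syn0net** needs no target data: rotation = argmax over the two rotation
  outputs, function = argmax over the three function outputs, the remaining
  basic-class outputs are ignored. Works identically on softmax or sigmoid
  output heads (monotone transforms of the same logits).
- **Sia5net**: branch = everything up to the 300-unit activation; the 50
  and output layers are dropped. One sigmoid unit on the element-wise
  |a−b| distance = 301 trainable parameters. Pairs: 50 % same-class
  (label 0); negatives (label 1) drawn 40 % function–function, 40 %
  rotation–rotation, 20 % other — operationalizing the design goal that the
  network should master separating functions from functions and rotations
  from rotations, while rotation-vs-function separation is unimportant
  (every combined movement contains one of each). Because the branch is
  fully frozen it runs in inference mode, each window's 300-unit feature is
  computed once, and head training operates on cached features — numerically
  identical to the twin forward pass. Classification: mean similarity per
  class over the q=5 queries, argmin (0 = same); a per-round majority vote
  is provided as the alternative aggregation.
- **FTnet**: the output layer is replaced by a 6-unit sigmoid layer
  (50·6 + 6 = 306 parameters; stage 1), then the 50-unit block is unlocked
  (15,050 + 100 BN = 15,456 total; stage 2 — the BN scale/shift of that
  block are part of the unlocked set). Loss is per-unit binary cross-entropy
  against one-hot targets; prediction is the sigmoid argmax. Locked
  sub-stacks run in inference mode during both stages: their dropout noise
  and batch statistics would otherwise corrupt the features the small head
  learns from (this also lets the stages train on cached representations).
  Stage 2 starts from the stage-1 weights.

## The synthetic generator

Channel c during a movement of class k:

    x_c(t) = env(t) · g_subj,c · g_orient,c · g_trial,c · a_trial ·
             G[k,c] · A · w_c(t)  +  B · b_c(t)  (+ optional 50 Hz hum)

with `env` a trapezoid (250 ms rise/fall), `G` the synergy bank (each basic
class strongly activates 2–4 of 10 channels; pairwise correlations < 0.95),
`w`, `b` independent 20–450 Hz band-limited unit-RMS Gaussian processes,
A = 25 µV per unit gain, B = 8 µV baseline. Combined-movement rows are the
per-channel maximum of their rotation and function rows (sum available for
sensitivity tests); max avoids double-counting shared channels. The
schedule reproduces the full acquisition protocol: 3 s rest, 2 s
preparation, 5 s basic / 7 s combined movements at 2048 Hz, repetitions ×
orientations in randomized order.

Variability model (all multiplicative log-normal): per-subject channel
gains SD 0.15, per-orientation SD 0.05, per-trial channel gains SD 0.15,
and a per-trial scalar amplitude factor SD 0.4. The last two are the load-
bearing choices: with stationary trials, a class is identified by its
channel-RMS fingerprint almost noiselessly from a single repetition and
every method saturates; per-trial variability — in particular the
common-mode amplitude factor, the synthetic analogue of contraction-force
variability — makes robust decoding require amplitude-invariant channel
patterns, which single-repetition training cannot deliver but multi-trial
(pre-)training can. These SDs were calibrated once, against the qualitative
orderings the generator must exhibit (supervision helps; pre-training beats
from-scratch training at one repetition; subject transfer helps a
data-limited target), not against any accuracy value, and then frozen.

What the generator does **not** model: motor-unit action potentials and
their firing statistics, class-specific spectral signatures,
nonstationarity within a contraction, electrode shift or impedance drift,
crosstalk structure beyond channel gains. Consequently, passing the
synthetic directional tests shows the architectures and training machinery
behave as designed under the synergy-superposition assumption — it does not
certify real-data accuracy levels.

One structural caveat: because synthetic combined movements satisfy the
superposition premise *exactly*, the zero-shot rule is close to optimal on
this testbed, and the supervised stages (Sia5net, FTnet) cannot be expected
to beat it there — on real data the premise holds only approximately, which
is precisely the gap those stages exist to close. The testbed therefore
asserts each stage against chance and against its like-for-like baseline
(FTnet vs from-scratch training on the same repetition), not against the
zero-shot rule.

## Desk-scale experiment harness

`myodecode.experiments` runs the full pipeline at sizes chosen for a single
CPU core, with non-overlapping 512-sample windows (thinned 2–4×), 4/8/8
conv filters, 12–20 epochs for full-network training, and the full
400/300-epoch staged schedules for the FTnet head stages (cheap on cached
features). The subject-transfer experiment uses a 5-subject cohort with all
three hand orientations: the target performs 3 repetitions per orientation
(a one-repetition budget therefore spans 3 trials per class — one per
orientation), the 4 source subjects 2 repetitions each; the sources, unlike
the target, are not data-limited. The task-transfer experiment uses one
subject, 5 basic repetitions and 2 combined repetitions in the sideway
orientation (combined movements are a sideway-only protocol). Accuracies
are averaged over 10 seeds. These sizes are the package's own
reproducibility tier; the CLI defaults (32/64/64 filters, 400/600-epoch
schedules) express the full-scale configuration.

## Known limitations

- The numpy engine is single-threaded-BLAS friendly but not GPU-capable;
  full-scale (400+ epoch, 40-subject) training is out of its intended range.
- Wilcoxon p-values use the exact distribution only up to n=25 subjects and
  drop zero differences; constant-difference comparisons return p=1 with a
  warning rather than failing.
- The Ninapro/Nearlab repository layouts are not parsed natively; recordings
  enter through the delimited-text + JSON interface or the simulator.
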