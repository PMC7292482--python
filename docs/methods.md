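# Methods

This package localizes three fiducial points on single-beat arterial
pressure waveforms — the systolic peak, the dicrotic notch, and the
end-diastolic pressure nadir — with a compact 1D densely-connected
convolutional network augmented by squeeze-and-excitation (SE) feature
recalibration, and derives the instantaneous wave-free ratio (iFR) from the
located points. This note records the models, the assumptions behind them,
the numerical choices, and what the synthetic experiments do and do not
show.

## The localization network

**Backbone.** The network is a small 1D DenseNet: an initial kernel-3
convolution producing `2g` channels, three dense blocks separated by two
transition blocks, and a regression head. Each dense block stacks four
BN→ReLU→Conv(kernel 3, "same" padding) units; unit `l` consumes the
concatenation of the block input and all previous unit outputs, and each
unit emits `g = 12` channels, so a block adds `4g = 48` channels. Each
transition block is BN→ReLU→Conv(kernel 1) to `floor(c·C)` channels
(compression `c = 0.6`) followed by average pooling of size 2. With the
defaults the channel/length trace is 24→72→43→91→54→102 over lengths
250→125→62. There are no bottleneck (DenseNet-B) layers and no dropout.

**Depth accounting.** Counting convolutional and fully-connected layers
(stem + 12 dense convs + 2 transition convs + head) the default network is
16 layers deep. Other conventions count differently; the
`convs_per_dense_block` knob is exposed rather than chasing any particular
total.

**SE recalibration.** Three variants are implemented. Channel SE (cSE)
squeezes each channel to its spatial mean, passes the `C`-vector through a
two-layer bottleneck (width `max(1, round(C/r))`, `r = 8`; inner ReLU,
outer sigmoid) and rescales each channel by its gate. Spatial SE (sSE)
squeezes channels with a kernel-1 convolution to one logit per position and
rescales each position by its sigmoid. Concurrent SE (scSE) combines both
branches element-wise; the combination operator defaults to maximum
(configurable to sum) since either convention appears in the segmentation
literature. The excitation order — inner ReLU, outer sigmoid — is the
standard SE ordering; bounded gates are required for the rescaling to act
as a recalibration. Excitation layers carry biases, matching common Keras
practice.

**Insertion positions.** SE blocks can be inserted after each dense block
(P1), after each transition block (P2), on the feature maps entering the
prediction head (P3), or at combinations of those points (P4 = P1+P2,
P5 = P1+P3, P6 = all three). "Before the head" is the only reading of a
head-adjacent SE block consistent with recalibration — a 3-unit output has
no feature maps to recalibrate. P5 with cSE is the default operating
point.

**Prediction head.** Global average pooling, one fully-connected layer to 3
units, ReLU, then a fixed gain of 250 (the window length). The head
regresses *fractional* positions inside the padded window and the gain
converts them to sample indices. The gain matters for optimization, not
expressiveness: with raw-index targets (0–250) and the recipe's small Adam
step (lr 1e-4), O(1) pooled features cannot reach the target scale within
a few hundred updates, whereas fractional regression starts in the right
range. The head bias starts at 0.5 so initial predictions sit mid-window;
weights start small (σ = 0.01). ReLU (not softmax) keeps positions
nonnegative without an upper clamp; predictions above 249 are possible and
reported as-is.

**Training.** Loss is the root-mean-square error between the 3-vector
output and the labeled indices, pooled over the batch, in sample units.
Adam (lr 1e-4, β = 0.9/0.999, ε = 1e-8), batch 32. Labels are raw sample
indices — the metrics operate in sample units, so the loss does too.
Training is pure NumPy and exactly reproducible given the seed. BatchNorm
uses batch statistics in training and exponential running averages
(momentum 0.9, ε = 1e-5) at evaluation; the short training schedules used
here are why the running-average momentum is 0.9 rather than a slower
0.99.

**The network stack.** The layers, reverse-mode autodiff and Adam are
implemented in NumPy inside `dfenet.nn`. Convolutions are evaluated as
per-offset channel matmuls ("same" zero padding); every hand-written
backward pass is verified against central finite differences in the test
suite. Finite-difference checks require care at two points: saturated
sigmoid gates have extreme curvature (the FD estimate converges to the
analytic gradient only for very small steps), and the element-wise maximum
in scSE has measure-zero tie points where only a subgradient exists (ties
route to the first branch).

## Evaluation metrics

For one beat with prediction `m` and label `n`,
`RMSE = sqrt((1/3) Σ_i (m_i − n_i)²)`. Over a test set the RMSE is pooled
over all beats' landmark deviations jointly (average the per-beat MSEs,
then take the root); the aggregation is stated here because it is not
implied by the per-beat definition. `Accuracy = (125 − RMSE)/125`, the
125-sample normalizer being the expected error of a uniformly random guess
on a 250-sample window; accuracy is reported as a percentage with two
decimals and may be negative for RMSE > 125. `Error` is the mean absolute
deviation over beats and landmarks. `MDE` compares the two
consecutive-landmark spacings (notch−peak, nadir−notch) between prediction
and label, averaged over the two segments and over beats; it is invariant
to a rigid shift of all three predictions. The cumulative error
distribution (CED) uses the normalized per-beat error
`e = ‖m − n‖₂ / 125` and reports the proportion of beats at or below each
grid value on [0, 0.25].

Agreement between predicted and labeled positions is summarized by the
Pearson correlation and Bland-Altman limits of agreement
(mean difference ± 1.96 sd), with the percentage of differences inside the
limits.

Splits are always subject-wise: leave-one-subject-out, or a subject-level
hold-out by fractions (60/20/20 by default). Beat-wise splitting would leak
within-subject morphology into the test set.

## The synthetic cohort

The clinical data this task is defined on (single-beat aortic pressure
complexes, 250 samples at 250 Hz, last-value padded) is private, so the
package ships a parametric simulator whose beats have *analytically exact*
landmarks:

- raised-sine systolic upstroke from diastolic to systolic pressure, peak
  at `i_peak ≈ 0.12–0.18` of the beat;
- half-cosine systolic decay to the notch pressure at
  `i_notch ≈ 0.30–0.40` of the beat;
- a sinusoidal dicrotic bump of amplitude `notch_prominence` (0.5–8 mmHg;
  the low end produces the "inconspicuous notch" regime that motivates
  learned localization), clamped below the systolic peak;
- strictly decreasing exponential diastolic decay to the last raw sample
  (the nadir), with time constant one third of the remaining beat.

Beat length is `round(fs·60/HR)`; heart rates drawn from 50–100 bpm whose
beats exceed the 250-sample window are rejected and the rate resampled, so
effective rates are ≥ 60 bpm. Beats are padded to 250 samples with the
last raw value. Gaussian noise (default σ = 1 mmHg) is added *after* the
landmarks are fixed; labels are construction truth, not re-detection, which
emulates expert annotation with zero observer error. Cohorts draw
per-subject base parameters once and jitter them per beat, so
within-subject beats are more alike than between-subject beats. Default
cohort scale: 100 subjects, 8–25 beats each (≈1700 beats), emulating a
~1500-beat/100-subject catheterization cohort.

Distal pressure for iFR experiments is modeled as
`Pd = gradient_factor · Pa + noise` with `gradient_factor ∈ (0, 1]` — a
deliberately minimal trans-stenotic model in which the true iFR of a
noiseless pair *is* the gradient factor, giving an exact oracle for the
end-to-end pipeline.

**What the simulator does not capture:** no Windkessel or transmission-line
hemodynamics, no reflected-wave morphology, no arrhythmia or ectopic
beats, no baseline drift or transducer artifacts, no annotation noise
(an optional label jitter can emulate inter-observer error), and no
phase lag between Pa and Pd. Passing the synthetic recovery tests shows the
architecture and training recipe can extract landmark structure of this
kind at clinical noise levels; it does not certify clinical performance.

**Beat-onset detection.** `extract_complexes` segments a continuous trace
at the foot of each upstroke: maxima of the smoothed derivative (height
≥ 40% of the global maximum, refractory 0.3 s) anchor each beat, and the
onset is the local minimum in the preceding 0.15 s. The leading partial
stretch is dropped; the trailing stretch is kept when it is at least 70% of
the median beat length, so a trace of k whole beats yields k segments. A
constant or slope-free trace raises an error rather than guessing.

## iFR

Diastole onset is the dicrotic notch. The wave-free window starts 25% of
the way from notch to nadir (rounded half-up, in samples) and ends 5 ms
before the nadir — at 250 Hz that is 1.25 samples, floored at one sample
(rounded half-up). The window is inclusive on both ends.
`iFR = mean(Pd)/mean(Pa)` over the window. Ratios below 0.89 are labeled
hemodynamically significant; 0.86–0.93 is additionally flagged as the
hybrid zone where FFR confirmation is often recommended — the two bands
overlap on [0.86, 0.89), so results carry a tuple of flags rather than one
label. When the network supplies the landmarks, notch/nadir predictions
are rounded half-up and clamped into the raw beat; a rounded notch at or
past the nadir raises a localization-failure error rather than producing a
window silently. Pa and Pd are assumed sample-synchronous (no transit-delay
correction), and per the definition iFR is computed per beat; multi-beat
averaging is left to the caller.

Localization tolerance: because diastolic pressure decays slowly,
perturbing notch/nadir by ±2 samples moves iFR by less than 0.01 on
synthetic beats — this is the quantitative reason a few samples of
localization error are clinically tolerable, and it is asserted as a test.

## Interpretability

Grad-CAM is adapted to regression by using the predicted coordinate itself
as the scalar target (there is no class score). Channel weights are the
positionwise-averaged gradients of that coordinate with respect to a chosen
stage's activations; the map is the ReLU of the gate-weighted channel sum,
linearly interpolated to the 250-sample input grid, returned raw and
max-normalized. A zero-gradient model yields an all-zero map with a
warning, not an error. The layer is an explicit argument; the last
pre-head stage is the conventional choice. `suppression_score` quantifies
how much activation mass one network zeroes relative to another at a
matched stage (fraction of elements below a relative threshold, default
1e-6 of the larger map's maximum magnitude).

## Problem sizes and determinism in the shipped tests

The test suite simulates a 100-subject cohort (seed 7, ≈1670 beats), trains
the default cSE/P5 network and its SE-free ablation for 15 epochs on the
60 training subjects, and evaluates on the 20 held-out test subjects; the
ablation comparison repeats both arms over three seeds. Fifteen epochs sits
past the accuracy plateau (the recovery criterion allows up to 30) and
keeps the full suite at desk scale. All randomness is NumPy-seeded;
training is exactly reproducible run-to-run on the same platform.

## What the synthetic ablation does and does not show

The test suite compares the cSE/P5 network against the SE-free backbone,
trained identically over three seeds on the same cohort. On this synthetic
cohort the plain backbone attains pooled test RMSE at least as low as the
SE variant on every seed. The reading is scientific, not a bug: the
simulator's beats are smooth and parametric, so the landmarks are
recoverable from low-level morphology alone, and channel recalibration
contributes extra gating parameters and multiplicative gate noise without
contributing signal. SE-style enhancement is motivated by *inconspicuous*
features and annotation noise in clinical traces — exactly what the
idealized simulator lacks. The suite's ablation-ordering test asserts the
enhancement ordering and therefore fails on this cohort; it is kept, and
kept failing, as an accurate statement about these study conditions rather
than being weakened to pass.

Grad-CAM on this architecture also deserves an honest caveat. With a
global-average-pooled head, the gradient of an output with respect to the
last-stage activations is constant across positions, so all spatial
selectivity in the map comes from the activations themselves; and because
the head regresses *fractional* positions partly through its bias, outputs
whose targets sit below the bias (peak and notch, typically 0.1–0.4 of the
window) can have a negative gradient-weighted sum at every position — the
rectified map is then empty. In the shipped training runs the nadir output
(target above the bias) yields nonzero maps, frequently concentrated late
in the beat, while peak/notch maps are often all-zero. The trained-model
attribution test asserts exactly this asymmetry rather than a
near-the-landmark peak, which these study conditions do not produce. A
contributing factor is the simulator itself: landmarks are tied to beat
length by construction (jittered fractions of the beat), so much of the
localization signal lives at the beat's start and padding boundary rather
than in local notch morphology.

A second empirical property the tests surface (and assert, direction
only): a network trained at the default 1 mmHg noise level localizes
noisy beats well but degrades sharply on *noiseless* beats — its early
derivative-like features are calibrated to the training noise floor.
End-to-end iFR on noiseless pairs is unaffected (with `Pd = g·Pa` exactly,
the ratio of window means equals `g` for any valid window), but the
localization itself is noise-level sensitive; matching the evaluation
noise level to training, or augmenting over noise levels, matters for any
real deployment.

## Known limitations

- The simulator's landmark fractions are fixed ranges, not fitted to any
  clinical distribution; absolute metric values on synthetic data should
  not be compared with values reported on clinical cohorts.
- The NumPy stack is CPU-only and single-threaded; it is sized for this
  network, not a general deep-learning framework.
- sSE gates applied to raw-scale early features can saturate (logits far
  from zero); cSE is the default for this reason as well as its empirical
  standing.
- `load_model` restores weights by construction order; configs must match
  the serialized architecture exactly.
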