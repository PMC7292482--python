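# dfenet

Landmark localization on single-beat arterial pressure waveforms with a 1D
densely-connected convolutional network enhanced by squeeze-and-excitation
(SE) recalibration, and computation of the instantaneous wave-free ratio
(iFR) from the located landmarks.

## The problem

Resting assessment of a coronary stenosis uses the iFR: the mean pressure
distal to the lesion divided by the mean aortic pressure over the diastolic
*wave-free period* — the window starting 25% of the way into diastole and
ending 5 ms before end-diastole. Computing it automatically requires
locating three fiducial points on each beat of the aortic pressure trace:

- the **systolic peak**,
- the **dicrotic notch** (aortic valve closure; the onset of diastole),
- the **end-diastolic pressure nadir**.

Pressure waveforms are morphologically sparse and the notch is often
inconspicuous, which defeats rule-based detectors. This package treats the
task as landmark regression: a compact 1D DenseNet (three dense blocks,
growth rate g=12; two transition blocks, compression c=0.6) with channel
squeeze-and-excitation blocks (reduction ratio r=8) inserted after each
dense block and before the regression head, predicting the three positions
in sample-index units on a 250-sample, 250 Hz beat. Performance is
summarized by the per-beat RMSE over the three landmarks,

    RMSE = sqrt( (1/3) Σᵢ (mᵢ − nᵢ)² ),    Accuracy = (125 − RMSE) / 125,

plus mean absolute error, the mean distance error between consecutive
landmark spacings (MDE), and the cumulative error distribution of
‖m − n‖₂/125.

Clinical beat data is private, so the package ships a synthetic waveform
simulator with analytically exact landmark labels (variable heart rate,
pressures, notch prominence down to barely visible, additive noise,
last-value padding). Every stage — simulation, training, evaluation, iFR,
attribution — is testable end to end without clinical data. The neural
network stack itself (reverse-mode autodiff, conv/BN/pooling layers, Adam)
is implemented in NumPy inside `dfenet.nn` and is verified against finite
differences in the test suite.

## Worked example

```python
import dfenet as df

# A 100-subject synthetic cohort (~1700 labeled beats), split by subject.
cohort = df.simulate_cohort(df.SimParams(seed=7), 100)
train_s, val_s, test_s = df.holdout_split(cohort, (0.6, 0.2, 0.2))

# Default network: cSE blocks at position P5, g=12, c=0.6, r=8.
model, history = df.train_on_dataset(
    cohort, train_s,
    net_config=df.NetworkConfig(),
    train_config=df.TrainConfig(epochs=15, batch_size=32,
                                learning_rate=1e-4, seed=0))

report = df.evaluate(model, cohort.for_subjects(test_s))
print(f"RMSE {report.rmse:.2f}  accuracy {100*report.accuracy:.2f}%  "
      f"error {report.error:.2f}  MDE {report.mde:.2f}")
```

Output from the run above:

```
RMSE 5.70  accuracy 95.44%  error 4.47  MDE 6.26
```

meaning: pooled over the 335 held-out beats, predicted landmarks deviate
from the true ones by 5.7 samples RMS (95.4% on the 125-sample accuracy
scale), 4.5 samples on average, and predicted landmark *spacings* are off
by 6.3 samples on average. Agreement with the labels on the same beats:
Pearson r = 0.9971, mean difference 0.21 samples, 95.1% of differences
inside the Bland-Altman 95% limits of agreement. From a trained model,
iFR for a proximal/distal beat pair is one call:

```python
rng = np.random.default_rng(0)
pa = df.simulate_complex(df.SimParams(noise_sd=0.0, seed=0), rng)
pd = df.make_distal_pressure(pa, gradient_factor=0.8, noise_sd=0.0, rng=rng)
result, positions = df.ifr_from_model(model, pa, pd)
print(result.ifr, result.bands)   # ~0.80 ('significant',)
```

Short narrative scripts, one per capability, live in `examples/`. A thin
CLI mirrors them: `dfenet simulate`, `dfenet train`, `dfenet evaluate`,
`dfenet ifr`, `dfenet explain`.

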