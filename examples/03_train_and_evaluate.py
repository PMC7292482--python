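"""Train the landmark-localization network and evaluate on held-out subjects.

A deliberately small run (20 subjects, 30 epochs, a few minutes); the full
study setting (100 subjects) is what the test suite exercises.
"""

import dfenet as df

cohort = df.simulate_cohort(df.SimParams(seed=7), n_subjects=20)
train_s, test_s = df.holdout_split(cohort, (0.75, 0.25))

model, history = df.train_on_dataset(
    cohort, train_s,
    net_config=df.NetworkConfig(),        # cSE blocks at position P5
    train_config=df.TrainConfig(epochs=30, seed=0))

print(f"training loss: {history[0]:.1f} -> {history[-1]:.1f} samples")
report = df.evaluate(model, cohort.for_subjects(test_s))
print(f"held-out subjects: RMSE {report.rmse:.2f} samples, "
      f"accuracy {100 * report.accuracy:.2f}%, "
      f"error {report.error:.2f}, MDE {report.mde:.2f}")
# Accuracy is (125 - RMSE)/125: the fraction of the 125-sample random-guess
# error that the network removes. Error is the mean absolute deviation per
# landmark; MDE compares predicted vs true landmark spacings.

X, y = cohort.for_subjects(test_s).arrays()
agree = df.agreement(model.predict(X).ravel(), y.ravel())
print(f"agreement: r = {agree.pearson_r:.4f}, "
      f"mean difference {agree.mean_difference:.2f} samples, "
      f"{agree.pct_within_loa:.1f}% within the 95% limits of agreement")
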