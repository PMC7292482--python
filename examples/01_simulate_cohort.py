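"""Simulate a labeled cohort of pressure-waveform complexes.

Builds a 10-subject cohort, prints its shape and one beat's landmarks, and
shows the last-value padding invariant.
"""

import numpy as np

import dfenet as df

cohort = df.simulate_cohort(df.SimParams(seed=42), n_subjects=10)
print(f"cohort: {len(cohort)} beats from {len(cohort.subjects)} subjects")

beat = cohort.complexes[0]
peak, notch, nadir = beat.landmarks
print(f"first beat: raw_length={beat.raw_length} samples, "
      f"peak@{peak} ({beat.samples[peak]:.1f} mmHg), "
      f"notch@{notch} ({beat.samples[notch]:.1f} mmHg), "
      f"nadir@{nadir} ({beat.samples[nadir]:.1f} mmHg)")
# The peak is the highest pressure of the beat; the notch marks diastole
# onset; the nadir is the last raw sample before padding.
pad = beat.samples[beat.raw_length:]
print(f"padding: {pad.size} samples, all equal to the last raw value: "
      f"{bool(np.all(pad == beat.samples[beat.raw_length - 1]))}")
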