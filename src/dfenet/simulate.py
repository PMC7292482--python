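"""Synthetic single-beat arterial pressure waveforms with known landmarks.

The generator produces one-beat aortic-pressure "complexes" that carry the
difficulty the landmark-localization task cares about — variable heart rate
(hence beat length), variable systolic/diastolic pressures, dicrotic notches
of controllable prominence down to barely visible, additive measurement
noise — while keeping the three landmark positions analytically exact:

* systolic **peak** at the top of a raised-sine upstroke,
* **dicrotic notch** at the local minimum between the systolic decay and a
  small sinusoidal dicrotic bump of amplitude ``notch_prominence``,
* end-diastolic **nadir** at the last raw sample of a strictly decreasing
  exponential diastolic decay.

Labels are the construction's indices, not re-detected from the noisy trace.
Beats are padded to 250 samples (250 Hz) with the beat's last value, matching
the preprocessing applied to clinical traces: extract complexes at the foot
of each upstroke, then last-value pad.

The simulator makes no hemodynamic (Windkessel) fidelity claim; it targets
landmark-detection difficulty, not physiological realism.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import find_peaks

__all__ = [
    "PAD_LENGTH",
    "SimParams",
    "WaveformComplex",
    "SubjectDataset",
    "simulate_complex",
    "simulate_cohort",
    "jitter_labels",
    "make_distal_pressure",
    "extract_complexes",
    "pad_complex",
]

#: Every complex is padded to this many samples (1 s at 250 Hz).
PAD_LENGTH = 250


@dataclass
class SimParams:
    """Cohort-level simulation parameters.

    Ranges are inclusive uniform intervals.  Defaults emulate a resting
    catheterization cohort: heart rate 50–100 bpm (beats longer than the
    250-sample window are resampled), systolic 90–180 mmHg, diastolic
    50–90 mmHg, dicrotic-notch prominence 0.5–8 mmHg (the low end yields
    inconspicuous notches), 1 mmHg additive Gaussian noise, 8–25 beats per
    subject.
    """

    heart_rate_range: tuple[float, float] = (50.0, 100.0)
    systolic_range: tuple[float, float] = (90.0, 180.0)
    diastolic_range: tuple[float, float] = (50.0, 90.0)
    notch_prominence_range: tuple[float, float] = (0.5, 8.0)
    noise_sd: float = 1.0
    fs: float = 250.0
    beats_per_subject_range: tuple[int, int] = (8, 25)
    seed: int = 0

    def __post_init__(self):
        for name in ("heart_rate_range", "systolic_range", "diastolic_range",
                     "notch_prominence_range", "beats_per_subject_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low must be <= high")
        if self.fs != 250.0:
            raise ValueError("sampling rate is fixed at 250 Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.beats_per_subject_range[0] < 1:
            raise ValueError("beats_per_subject_range must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        for name in ("heart_rate_range", "systolic_range", "diastolic_range",
                     "notch_prominence_range", "beats_per_subject_range"):
            if name in d and d[name] is not None:
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimParams":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class WaveformComplex:
    """One padded 250-sample pressure beat in mmHg.

    ``landmarks`` is an optional (peak, notch, nadir) triple of 0-based
    indices, each < ``raw_length``; samples at indices >= ``raw_length``
    all equal the last raw sample (last-value padding).
    """

    samples: np.ndarray
    raw_length: int
    landmarks: tuple[int, int, int] | None = None
    subject_id: str = "s0"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (PAD_LENGTH,):
            raise ValueError(f"samples must have length {PAD_LENGTH}")
        if not (1 <= self.raw_length <= PAD_LENGTH):
            raise ValueError("raw_length must be in [1, 250]")
        if self.landmarks is not None:
            peak, notch, nadir = self.landmarks
            if not (0 <= peak < notch < nadir < self.raw_length):
                raise ValueError(
                    "landmarks must satisfy 0 <= peak < notch < nadir < raw_length"
                )
            self.landmarks = (int(peak), int(notch), int(nadir))

    @property
    def raw_samples(self) -> np.ndarray:
        return self.samples[: self.raw_length]


@dataclass
class SubjectDataset:
    """A cohort of labeled complexes grouped by subject."""

    complexes: list[WaveformComplex]
    subjects: list[str]
    provenance: SimParams | str = "external"

    def __post_init__(self):
        known = set(self.subjects)
        seen = {c.subject_id for c in self.complexes}
        if not seen <= known:
            raise ValueError("complex subject_id not listed in subjects")
        missing = known - seen
        if missing:
            raise ValueError(f"subjects with no complexes: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.complexes)

    def for_subjects(self, subjects) -> "SubjectDataset":
        subjects = list(subjects)
        keep = set(subjects)
        return SubjectDataset(
            [c for c in self.complexes if c.subject_id in keep],
            subjects,
            self.provenance,
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y): beats as (N, 250) and landmark labels as (N, 3) floats."""
        X = np.stack([c.samples for c in self.complexes])
        labels = []
        for c in self.complexes:
            if c.landmarks is None:
                raise ValueError("dataset contains unlabeled complexes")
            labels.append(c.landmarks)
        return X, np.asarray(labels, dtype=np.float64)

    # CSV round trip ---------------------------------------------------------

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        rows = []
        for c in self.complexes:
            row: dict = {"subject_id": c.subject_id, "raw_length": c.raw_length}
            if c.landmarks is None:
                row.update(peak=np.nan, notch=np.nan, nadir=np.nan)
            else:
                row.update(zip(("peak", "notch", "nadir"), c.landmarks))
            row.update({f"s{i}": c.samples[i] for i in range(PAD_LENGTH)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "SubjectDataset":
        df = pd.read_csv(path)
        sample_cols = [f"s{i}" for i in range(PAD_LENGTH)]
        complexes = []
        subjects: list[str] = []
        for _, row in df.iterrows():
            lm = None
            if not (pd.isna(row["peak"]) or pd.isna(row["notch"]) or pd.isna(row["nadir"])):
                lm = (int(row["peak"]), int(row["notch"]), int(row["nadir"]))
            sid = str(row["subject_id"])
            complexes.append(WaveformComplex(
                samples=row[sample_cols].to_numpy(dtype=np.float64),
                raw_length=int(row["raw_length"]),
                landmarks=lm,
                subject_id=sid,
            ))
            if sid not in subjects:
                subjects.append(sid)
        return cls(complexes, subjects, "external")


# ---------------------------------------------------------------------------
# beat construction
# ---------------------------------------------------------------------------

def _draw_beat_params(params: SimParams, rng: np.random.Generator,
                      base: dict | None = None) -> dict:
    """Draw one beat's generative parameters, optionally jittered around a
    per-subject base (within-subject beats are more alike than across)."""

    def jitter(val, sd, lo, hi):
        return float(np.clip(val + rng.normal(0.0, sd), lo, hi))

    if base is None:
        hr = rng.uniform(*params.heart_rate_range)
        dia = rng.uniform(*params.diastolic_range)
        sys_ = rng.uniform(*params.systolic_range)
        prom = rng.uniform(*params.notch_prominence_range)
        frac_peak = rng.uniform(0.12, 0.18)
        frac_notch = rng.uniform(0.30, 0.40)
        notch_depth = rng.uniform(0.20, 0.35)
    else:
        hr = jitter(base["hr"], 2.0, *params.heart_rate_range)
        dia = jitter(base["dia"], 2.5, *params.diastolic_range)
        sys_ = jitter(base["sys"], 4.0, *params.systolic_range)
        prom = jitter(base["prom"], 0.3, *params.notch_prominence_range)
        frac_peak = jitter(base["frac_peak"], 0.005, 0.10, 0.20)
        frac_notch = jitter(base["frac_notch"], 0.01, 0.28, 0.42)
        notch_depth = jitter(base["notch_depth"], 0.01, 0.18, 0.38)
    sys_ = max(sys_, dia + 20.0)  # enforce a physiological pulse pressure
    return dict(hr=hr, dia=dia, sys=sys_, prom=prom, frac_peak=frac_peak,
                frac_notch=frac_notch, notch_depth=notch_depth)


def _build_beat(p: dict, fs: float) -> tuple[np.ndarray, tuple[int, int, int]] | None:
    """Deterministic noiseless beat from generative parameters, or None if
    the implied length exceeds the 250-sample window."""
    length = int(round(fs * 60.0 / p["hr"]))
    if length > PAD_LENGTH:
        return None
    length = max(length, 100)  # HR range keeps us well above this in practice
    i_peak = max(1, int(round(p["frac_peak"] * length)))
    i_notch = max(i_peak + 5, int(round(p["frac_notch"] * length)))
    i_bump = min(i_notch + max(3, int(round(0.06 * length))), length - 10)
    if i_bump <= i_notch:
        return None
    pulse = p["sys"] - p["dia"]
    p_notch = p["dia"] + p["notch_depth"] * pulse
    prom = min(p["prom"], 0.8 * (p["sys"] - p_notch))
    p_inf = p["dia"] - 0.05 * pulse
    tau = (length - 1 - i_bump) / 3.0

    t = np.arange(length, dtype=np.float64)
    beat = np.empty(length)
    up = t[: i_peak + 1]
    beat[: i_peak + 1] = p["dia"] + pulse * np.sin(np.pi * up / (2.0 * i_peak))
    seg = t[i_peak + 1: i_notch + 1] - i_peak
    beat[i_peak + 1: i_notch + 1] = p_notch + (p["sys"] - p_notch) * np.cos(
        np.pi / 2.0 * seg / (i_notch - i_peak)
    )
    seg = t[i_notch + 1: i_bump + 1] - i_notch
    beat[i_notch + 1: i_bump + 1] = p_notch + prom * np.sin(
        np.pi / 2.0 * seg / (i_bump - i_notch)
    )
    seg = t[i_bump + 1:] - i_bump
    beat[i_bump + 1:] = p_inf + (p_notch + prom - p_inf) * np.exp(-seg / tau)
    return beat, (i_peak, i_notch, length - 1)


def simulate_complex(params: SimParams, rng: np.random.Generator,
                     subject_id: str = "s0",
                     base: dict | None = None) -> WaveformComplex:
    """Simulate one labeled complex.

    Heart rates implying beats longer than the 250-sample window are
    rejected and resampled (up to 100 tries).  Landmark labels are the
    construction's exact indices; noise never moves them.
    """
    p = _draw_beat_params(params, rng, base)
    for _ in range(100):
        built = _build_beat(p, params.fs)
        if built is not None:
            beat, landmarks = built
            if params.noise_sd > 0:
                beat = beat + rng.normal(0.0, params.noise_sd, size=beat.shape)
            return pad_complex(beat, landmarks=landmarks, subject_id=subject_id)
        p["hr"] = rng.uniform(*params.heart_rate_range)  # resample heart rate only
    raise RuntimeError(
        "could not draw a beat of <= 250 samples in 100 tries; "
        "check heart_rate_range"
    )


def simulate_cohort(params: SimParams, n_subjects: int) -> SubjectDataset:
    """Simulate a cohort: per-subject base parameters drawn once, then
    jittered per beat, so within-subject beats resemble each other."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(params.seed)
    complexes: list[WaveformComplex] = []
    subjects: list[str] = []
    width = len(str(n_subjects))
    for s in range(n_subjects):
        sid = f"s{s:0{width}d}"
        subjects.append(sid)
        base = _draw_beat_params(params, rng)
        for _ in range(100):  # subject base heart rate must fit the window
            if int(round(params.fs * 60.0 / base["hr"])) <= PAD_LENGTH:
                break
            base = _draw_beat_params(params, rng)
        lo, hi = params.beats_per_subject_range
        n_beats = int(rng.integers(lo, hi + 1))
        for _ in range(n_beats):
            complexes.append(simulate_complex(params, rng, subject_id=sid, base=base))
    return SubjectDataset(complexes, subjects, provenance=params)


def jitter_labels(dataset: SubjectDataset, max_shift: int,
                  rng: np.random.Generator) -> SubjectDataset:
    """Perturb every landmark by a uniform integer shift in [-k, k].

    Emulates inter-observer annotation error for robustness experiments.
    Shifts are clipped so the (peak < notch < nadir < raw_length) ordering
    survives; unlabeled complexes pass through unchanged.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    out = []
    for c in dataset.complexes:
        if c.landmarks is None:
            out.append(c)
            continue
        peak, notch, nadir = c.landmarks
        shifts = rng.integers(-max_shift, max_shift + 1, size=3)
        peak = int(np.clip(peak + shifts[0], 0, c.raw_length - 3))
        notch = int(np.clip(notch + shifts[1], peak + 1, c.raw_length - 2))
        nadir = int(np.clip(nadir + shifts[2], notch + 1, c.raw_length - 1))
        out.append(WaveformComplex(c.samples.copy(), c.raw_length,
                                   (peak, notch, nadir), c.subject_id))
    return SubjectDataset(out, list(dataset.subjects), dataset.provenance)


def make_distal_pressure(pa: WaveformComplex, gradient_factor: float,
                         noise_sd: float, rng: np.random.Generator) -> WaveformComplex:
    """Synthetic distal pressure: Pd = gradient_factor * Pa + noise.

    ``gradient_factor`` in (0, 1] models the trans-stenotic pressure drop.
    Landmarks are copied from Pa; the padded tail is re-padded with the last
    raw value so the padding invariant holds after noise.
    """
    if not (0.0 < gradient_factor <= 1.0):
        raise ValueError("gradient_factor must be in (0, 1]")
    if pa.landmarks is None:
        raise ValueError("pa must carry landmarks")
    raw = gradient_factor * pa.raw_samples
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    return pad_complex(raw, landmarks=pa.landmarks, subject_id=pa.subject_id)


# ---------------------------------------------------------------------------
# preprocessing of continuous traces
# ---------------------------------------------------------------------------

def extract_complexes(trace: np.ndarray, fs: float = 250.0) -> list[np.ndarray]:
    """Split a quasi-periodic pressure trace into single-beat segments.

    Beat onsets are the feet of the upstrokes: the local minimum immediately
    preceding each maximal-positive-slope point.  Segments run from onset to
    onset; a partial leading stretch before the first onset is dropped, and
    the trailing stretch after the last onset is kept only when it is at
    least 70% of the median beat length (a lone detected onset keeps its
    trailing segment, so a single-beat trace yields one segment).
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1 or x.size < 50:
        raise ValueError("trace must be a 1D array of at least 50 samples")
    if np.ptp(x) < 1e-9:
        raise ValueError("no detectable periodicity: trace is constant")
    # light smoothing so slope peaks are robust to sample noise;
    # edge-replicated padding avoids spurious boundary slope spikes
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(np.pad(x, 2, mode="edge"), kernel, mode="valid")
    deriv = np.gradient(smooth)
    max_slope = deriv.max()
    if max_slope <= 0 or max_slope < 0.02 * np.ptp(x):
        raise ValueError("no detectable periodicity: no rising edges found")
    min_period = int(0.3 * fs)  # refractory: < 200 bpm
    peaks, _ = find_peaks(deriv, height=0.4 * max_slope, distance=min_period)
    if peaks.size == 0:
        raise ValueError("no detectable periodicity: no upstrokes detected")
    onsets = []
    lookback = int(0.15 * fs)
    for pk in peaks:
        # walk back from the maximal slope to the foot of the upstroke:
        # the first sample whose slope falls below 10% of the peak slope
        lo = max(0, pk - lookback)
        i = pk
        thresh = 0.1 * deriv[pk]
        while i > lo and deriv[i - 1] > thresh:
            i -= 1
        onsets.append(i)
    onsets = sorted(set(onsets))
    segments = [x[a:b] for a, b in zip(onsets[:-1], onsets[1:])]
    tail = x[onsets[-1]:]
    if segments:
        median_len = float(np.median([len(s) for s in segments]))
        if len(tail) >= 0.7 * median_len:
            segments.append(tail)
    elif len(tail) >= min_period:
        segments.append(tail)
    return segments


def pad_complex(beat: np.ndarray, landmarks: tuple[int, int, int] | None = None,
                subject_id: str = "s0") -> WaveformComplex:
    """Pad an unpadded beat to 250 samples with its last value."""
    beat = np.asarray(beat, dtype=np.float64)
    if beat.ndim != 1 or beat.size < 1:
        raise ValueError("beat must be a nonempty 1D array")
    if beat.size > PAD_LENGTH:
        raise ValueError(
            f"beat of length {beat.size} exceeds the {PAD_LENGTH}-sample window"
        )
    samples = np.concatenate([
        beat, np.full(PAD_LENGTH - beat.size, beat[-1])
    ])
    return WaveformComplex(samples=samples, raw_length=beat.size,
                           landmarks=landmarks, subject_id=subject_id)
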