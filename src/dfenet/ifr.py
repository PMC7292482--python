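"""Instantaneous wave-free ratio (iFR) from located landmarks.

iFR is the mean distal coronary pressure divided by the mean aortic pressure
over the diastolic wave-free period: the window beginning 25% of the way
into diastole (diastole onset = dicrotic notch) and ending 5 ms before
end-diastole.  Lesions with iFR < 0.89 are treated as hemodynamically
significant; 0.86–0.93 is a hybrid zone of uncertainty where confirmation
with FFR is often recommended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DFENet
from .simulate import WaveformComplex

__all__ = [
    "SIGNIFICANCE_THRESHOLD",
    "HYBRID_ZONE",
    "WaveFreeWindow",
    "IfrResult",
    "wave_free_window",
    "compute_ifr",
    "ifr_from_model",
    "classify_ifr",
]

SIGNIFICANCE_THRESHOLD = 0.89
HYBRID_ZONE = (0.86, 0.93)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WaveFreeWindow:
    """Inclusive [start, end] sample window of the wave-free period."""

    start: int
    end: int
    fs: float = 250.0

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("window must contain at least 2 samples")


@dataclass(frozen=True)
class IfrResult:
    mean_pa: float
    mean_pd: float
    ifr: float
    bands: tuple[str, ...]
    window: WaveFreeWindow

    def to_dict(self) -> dict:
        return {
            "mean_pa": self.mean_pa,
            "mean_pd": self.mean_pd,
            "ifr": self.ifr,
            "bands": list(self.bands),
            "window": {"start": self.window.start, "end": self.window.end,
                       "fs": self.window.fs},
        }


def classify_ifr(ifr: float) -> tuple[str, ...]:
    """Decision bands; the hybrid zone can overlap either primary band."""
    bands = ["significant" if ifr < SIGNIFICANCE_THRESHOLD else "non-significant"]
    if HYBRID_ZONE[0] <= ifr <= HYBRID_ZONE[1]:
        bands.append("hybrid-zone")
    return tuple(bands)


def wave_free_window(notch: int, nadir: int, fs: float = 250.0) -> WaveFreeWindow:
    """Wave-free period from the dicrotic notch and end-diastolic nadir.

    start = notch + round(0.25 * (nadir - notch)); end = nadir minus the
    number of samples in 5 ms (at least one).  Rounding is half-up.
    """
    if not (notch < nadir):
        raise ValueError(f"need notch < nadir, got notch={notch}, nadir={nadir}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    start = notch + _round_half_up(0.25 * (nadir - notch))
    end = nadir - max(1, _round_half_up(0.005 * fs))
    if start >= end:
        raise ValueError(
            f"degenerate diastole: window [{start}, {end}] from "
            f"notch={notch}, nadir={nadir} has fewer than 2 samples"
        )
    return WaveFreeWindow(start=start, end=end, fs=fs)


def compute_ifr(pa: WaveformComplex, pd: WaveformComplex,
                window: WaveFreeWindow) -> IfrResult:
    """iFR = mean(Pd) / mean(Pa) over the inclusive wave-free window."""
    if pa.raw_length != pd.raw_length:
        raise ValueError("Pa and Pd must share raw_length")
    if not (0 <= window.start and window.end < pa.raw_length):
        raise ValueError(
            f"window [{window.start}, {window.end}] outside the raw beat "
            f"(raw_length={pa.raw_length})"
        )
    sl = slice(window.start, window.end + 1)
    mean_pa = float(np.mean(pa.samples[sl]))
    mean_pd = float(np.mean(pd.samples[sl]))
    if mean_pa <= 0:
        raise ValueError("mean aortic pressure must be positive")
    ifr = mean_pd / mean_pa
    return IfrResult(mean_pa=mean_pa, mean_pd=mean_pd, ifr=ifr,
                     bands=classify_ifr(ifr), window=window)


def ifr_from_model(model: DFENet, pa: WaveformComplex,
                   pd: WaveformComplex) -> tuple[IfrResult, np.ndarray]:
    """Locate landmarks on Pa with the network, then compute iFR.

    The continuous notch/nadir predictions are rounded to the nearest
    integer and clamped into the raw beat.  A rounded notch at or past the
    rounded nadir is flagged as a localization failure.  Returns the iFR
    result and the raw 3-vector of predicted positions for audit.
    """
    positions = model.predict(pa.samples)
    notch = int(np.clip(_round_half_up(positions[1]), 0, pa.raw_length - 1))
    nadir = int(np.clip(_round_half_up(positions[2]), 0, pa.raw_length - 1))
    if notch >= nadir:
        raise ValueError(
            f"localization failure: predicted notch {notch} >= nadir {nadir}"
        )
    window = wave_free_window(notch, nadir, fs=250.0)
    return compute_ifr(pa, pd, window), positions
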