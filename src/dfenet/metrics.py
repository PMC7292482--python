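"""Evaluation metrics for landmark localization.

All positions are in sample-index units on the 250-sample window.  With three
landmarks per beat the per-beat root-mean-square error is

    RMSE = sqrt( (1/3) * sum_i (m_i - n_i)^2 )

and accuracy is defined against the 125-sample expectation of a random guess:

    Accuracy = (125 - RMSE) / 125.

Error is the mean absolute deviation over beats and landmarks; MDE compares
the two consecutive landmark *distances* (notch-peak, nadir-notch) between
prediction and label; the CED curve is the cumulative distribution of the
normalized per-beat error ||pred - label||_2 / 125.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HALF_WINDOW",
    "MetricsReport",
    "AgreementReport",
    "rmse",
    "accuracy",
    "avg_error",
    "mde",
    "ced_curve",
    "agreement",
]

#: Normalization constant: half of the 250-sample window.
HALF_WINDOW = 125.0


def _check(preds, labels) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.shape != labels.shape:
        raise ValueError(f"shape mismatch: {preds.shape} vs {labels.shape}")
    if not (np.all(np.isfinite(preds)) and np.all(np.isfinite(labels))):
        raise ValueError("non-finite positions")
    return preds, labels


def rmse(pred, label) -> float:
    """Root-mean-square error over landmark deviations (pooled if 2D)."""
    pred, label = _check(pred, label)
    return float(np.sqrt(np.mean((pred - label) ** 2)))


def accuracy(rmse_value: float) -> float:
    """(125 - RMSE) / 125 as a fraction; negative if RMSE > 125."""
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    return (HALF_WINDOW - rmse_value) / HALF_WINDOW


def avg_error(preds, labels) -> float:
    """Mean absolute deviation over beats and landmarks."""
    preds, labels = _check(preds, labels)
    return float(np.mean(np.abs(preds - labels)))


def mde(preds, labels) -> float:
    """Mean distance error between consecutive-landmark spacings.

    For each beat the two spacings (notch - peak, nadir - notch) are compared
    between prediction and label; their absolute differences are averaged
    over the two segments, then over beats.
    """
    preds, labels = _check(preds, labels)
    preds = np.atleast_2d(preds)
    labels = np.atleast_2d(labels)
    d_pred = np.diff(preds, axis=1)
    d_label = np.diff(labels, axis=1)
    return float(np.mean(np.abs(d_pred - d_label)))


def ced_curve(preds, labels, grid=None) -> list[tuple[float, float]]:
    """Cumulative error distribution over the normalized per-beat error.

    The per-beat error is the Euclidean norm of the 3-landmark error vector
    divided by 125; each grid point maps to the proportion of beats at or
    below it.
    """
    preds, labels = _check(preds, labels)
    preds = np.atleast_2d(preds)
    labels = np.atleast_2d(labels)
    if grid is None:
        grid = np.linspace(0.0, 0.25, 26)
    grid = np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    e = np.linalg.norm(preds - labels, axis=1) / HALF_WINDOW
    return [(float(g), float(np.mean(e <= g))) for g in grid]


@dataclass
class MetricsReport:
    """The four localization metrics plus the CED curve."""

    rmse: float
    accuracy: float
    error: float
    mde: float
    ced: list[tuple[float, float]] = field(default_factory=list)
    n_beats: int = 0

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "accuracy": self.accuracy,
            "accuracy_percent": round(100.0 * self.accuracy, 2),
            "error": self.error,
            "mde": self.mde,
            "ced": [[e, p] for e, p in self.ced],
            "n_beats": self.n_beats,
        }


@dataclass
class AgreementReport:
    """Pearson correlation and Bland-Altman limits of agreement."""

    pearson_r: float
    mean_difference: float
    loa_low: float
    loa_high: float
    pct_within_loa: float

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "mean_difference": self.mean_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pct_within_loa": self.pct_within_loa,
        }


def agreement(preds, labels) -> AgreementReport:
    """Correlation + Bland-Altman agreement between flat position vectors.

    Limits of agreement are mean difference +/- 1.96 sd of the differences;
    ``pct_within_loa`` is the percentage of differences inside the limits.
    Zero variance in either input makes the correlation undefined (NaN).
    """
    preds, labels = _check(preds, labels)
    preds, labels = preds.ravel(), labels.ravel()
    if preds.size < 3:
        raise ValueError("agreement needs at least 3 paired positions")
    if np.std(preds) == 0 or np.std(labels) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(preds, labels).statistic)
    d = preds - labels
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    half = 1.96 * sd_d
    within = float(np.mean(np.abs(d - mean_d) <= half) * 100.0)
    return AgreementReport(
        pearson_r=r,
        mean_difference=mean_d,
        loa_low=mean_d - half,
        loa_high=mean_d + half,
        pct_within_loa=within,
    )
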