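"""Interpretability: stage feature maps and 1D Grad-CAM for the regression head.

Grad-CAM for a regressed landmark uses the predicted coordinate itself as
the scalar target: channel weights are the positionwise-averaged gradients
of that coordinate with respect to a convolutional stage's activations, the
map is the ReLU of the weighted channel sum, and it is linearly upsampled
to the 250-sample input grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import DFENet
from .nn import Tensor, no_grad
from .simulate import PAD_LENGTH, WaveformComplex

__all__ = [
    "AttributionMap",
    "extract_feature_maps",
    "grad_cam_1d",
    "suppression_score",
]

LANDMARK_NAMES = ("peak", "notch", "nadir")


@dataclass
class AttributionMap:
    """Nonnegative per-position importance on the 250-sample input grid."""

    values: np.ndarray
    normalized: np.ndarray
    landmark: str
    layer: str

    def __post_init__(self):
        if self.values.shape != (PAD_LENGTH,):
            raise ValueError(f"attribution map must have length {PAD_LENGTH}")


def _beat_array(beat: WaveformComplex | np.ndarray) -> np.ndarray:
    if isinstance(beat, WaveformComplex):
        return beat.samples
    return np.asarray(beat, dtype=np.float64)


def extract_feature_maps(model: DFENet, beat: WaveformComplex | np.ndarray,
                         stage: str) -> np.ndarray:
    """Post-block activations (channels x length) for one beat, eval mode."""
    x = _beat_array(beat)
    model.eval()
    record: dict[str, Tensor] = {}
    with no_grad():
        model.forward(Tensor(x[None, None, :]), record=record)
    if stage not in record:
        raise KeyError(
            f"unknown stage {stage!r}; valid stages: {model.stage_names()}"
        )
    return record[stage].data[0]


def grad_cam_1d(model: DFENet, beat: WaveformComplex | np.ndarray,
                landmark_index: int, layer: str) -> AttributionMap:
    """1D Grad-CAM of one predicted landmark with respect to ``layer``.

    Channel weights are the mean over positions of the gradient of the
    predicted coordinate; the CAM is ReLU(sum_c weight_c * activation_c),
    linearly interpolated to length 250.  A model whose head passes no
    gradient yields an all-zero map with a warning.
    """
    if landmark_index not in (0, 1, 2):
        raise ValueError("landmark_index must be 0 (peak), 1 (notch) or 2 (nadir)")
    x = _beat_array(beat)
    model.eval()
    record: dict[str, Tensor] = {}
    out = model.forward(Tensor(x[None, None, :]), record=record)
    if layer not in record:
        raise KeyError(
            f"unknown layer {layer!r}; valid stages: {model.stage_names()}"
        )
    target = record[layer]
    model.zero_grad()
    seed = np.zeros_like(out.data)
    seed[0, landmark_index] = 1.0
    out.backward(seed)
    grad = target.grad
    acts = target.data[0]  # (C, W)
    if grad is None or not np.any(grad):
        warnings.warn(
            "Grad-CAM: gradient is zero everywhere; returning an all-zero map",
            RuntimeWarning,
        )
        cam_small = np.zeros(acts.shape[1])
    else:
        weights = grad[0].mean(axis=1)  # (C,)
        cam_small = np.maximum(weights @ acts, 0.0)
    src = np.linspace(0.0, PAD_LENGTH - 1, num=cam_small.size)
    cam = np.interp(np.arange(PAD_LENGTH, dtype=np.float64), src, cam_small)
    peak_val = cam.max()
    normalized = cam / peak_val if peak_val > 0 else cam.copy()
    return AttributionMap(values=cam, normalized=normalized,
                          landmark=LANDMARK_NAMES[landmark_index], layer=layer)


def suppression_score(maps_a: np.ndarray, maps_b: np.ndarray,
                      eps_rel: float = 1e-6) -> float:
    """Fraction of elements near zero in ``maps_a`` but active in ``maps_b``.

    The threshold is ``eps_rel`` times the larger of the two maps' maximum
    magnitudes.  Quantifies how much of one network's activation mass another
    network (e.g. one with SE recalibration) suppresses at a matched stage.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    eps = eps_rel * max(np.abs(a).max(), np.abs(b).max())
    if eps == 0.0:
        return 0.0
    return float(np.mean((np.abs(a) < eps) & (np.abs(b) >= eps)))
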