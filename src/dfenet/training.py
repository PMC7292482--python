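"""Training and evaluation under subject-wise splits.

The loss is the root-mean-square error between the 3-unit network output and
the labeled landmark indices, pooled over the batch, minimized with Adam
(lr 1e-4, batch 32 by default).  Splits are always subject-wise — all beats
from a subject land on the same side — either leave-one-subject-out or a
subject-level hold-out by fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .metrics import MetricsReport, accuracy, avg_error, ced_curve, mde, rmse
from .model import DFENet, build_dfenet
from .nn import Adam, Tensor, no_grad
from .simulate import SubjectDataset

__all__ = [
    "TrainConfig",
    "loo_splits",
    "holdout_split",
    "train_model",
    "evaluate",
    "train_on_dataset",
]


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def loo_splits(dataset: SubjectDataset):
    """Leave-one-subject-out folds: (train_subjects, test_subject) per subject."""
    subjects = list(dataset.subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    for held_out in subjects:
        yield [s for s in subjects if s != held_out], held_out


def holdout_split(dataset: SubjectDataset, fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
                  shuffle_seed: int | None = None) -> list[list[str]]:
    """Partition subjects into consecutive groups by fractions (e.g. 60/20/20).

    Fractions must sum to 1; the split is by subject, never by beat.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    subjects = list(dataset.subjects)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(subjects)
    bounds = np.floor(np.cumsum(fractions) * len(subjects)).astype(int)
    groups, start = [], 0
    for b in bounds:
        groups.append(subjects[start:b])
        start = b
    return groups


def _rmse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean().sqrt()


def train_model(model: DFENet, train_set: SubjectDataset,
                config: TrainConfig | None = None) -> list[float]:
    """Train in place; returns the per-epoch mean training loss (samples).

    Fully deterministic given the training seed (pure NumPy backend).
    Raises if the training set contains unlabeled beats.
    """
    if config is None:
        config = TrainConfig()
    X, y = train_set.arrays()  # raises on unlabeled beats
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    model.train()
    history: list[float] = []
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            xb = Tensor(X[idx][:, None, :])
            pred = model(xb)
            loss = _rmse_loss(pred, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    model.eval()
    return history


def evaluate(model: DFENet, test_set: SubjectDataset,
             batch_size: int = 128) -> MetricsReport:
    """All localization metrics over a labeled test set.

    RMSE is pooled over every landmark deviation of every beat (per-beat
    mean squared errors averaged, then rooted); accuracy derives from the
    pooled RMSE.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    X, y = test_set.arrays()
    model.eval()
    preds = []
    with no_grad():
        for start in range(0, X.shape[0], batch_size):
            xb = Tensor(X[start: start + batch_size][:, None, :])
            preds.append(model(xb).data)
    preds = np.concatenate(preds, axis=0)
    pooled = rmse(preds, y)
    return MetricsReport(
        rmse=pooled,
        accuracy=accuracy(pooled),
        error=avg_error(preds, y),
        mde=mde(preds, y),
        ced=ced_curve(preds, y),
        n_beats=X.shape[0],
    )


def train_on_dataset(dataset: SubjectDataset,
                     train_subjects: list[str],
                     net_config: NetworkConfig | None = None,
                     train_config: TrainConfig | None = None,
                     init_seed: int | None = None) -> tuple[DFENet, list[float]]:
    """Convenience: build a network and train it on the given subjects."""
    if train_config is None:
        train_config = TrainConfig()
    if init_seed is None:
        init_seed = train_config.seed
    model = build_dfenet(net_config, seed=init_seed)
    history = train_model(model, dataset.for_subjects(train_subjects), train_config)
    return model, history
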