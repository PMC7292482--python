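"""Assembly of the full landmark-localization network.

The network is a compact 1D densely-connected architecture: an initial
kernel-3 convolution, three dense blocks separated by two transition blocks,
and a prediction head that regresses the three landmark positions (systolic
peak, dicrotic notch, end-diastolic nadir) in sample-index units.
Squeeze-and-excitation blocks are inserted at one of six positions P1–P6
relative to the dense/transition/prediction blocks:

========  ====================================================
P1        after each dense block
P2        after each transition block
P3        on the feature maps entering the prediction head
P4        after dense and transition blocks
P5        after dense blocks and before the head (recommended)
P6        all three insertion points
========  ====================================================

With the default configuration (growth 12, compression 0.6, 4 convs per
dense block, 24 stem channels) the channel/length trace is
24→72→43→91→54→102 over lengths 250→125→62.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .blocks import (
    DenseBlock,
    PredictionBlock,
    TransitionBlock,
    make_se_block,
)
from .nn import Conv1d, Module, Tensor, no_grad

__all__ = ["DFENet", "build_dfenet", "save_model", "load_model"]


class DFENet(Module):
    """The assembled network.  Use :func:`build_dfenet` to construct one."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        cfg = config
        c = cfg.init_channels
        self.stem = Conv1d(1, c, cfg.kernel_size, rng)
        self.dense_blocks: list[DenseBlock] = []
        self.se_dense: list[Module | None] = []
        self.transitions: list[TransitionBlock] = []
        self.se_transition: list[Module | None] = []
        length = cfg.input_length
        self._trace: list[tuple[str, int, int]] = [("stem", c, length)]
        for i in range(cfg.n_dense_blocks):
            db = DenseBlock(c, cfg.growth_rate, cfg.convs_per_dense_block, rng)
            self.dense_blocks.append(db)
            c = db.out_channels
            self._trace.append((f"dense{i + 1}", c, length))
            self.se_dense.append(
                make_se_block(cfg.se_variant, c, cfg.reduction_ratio, rng)
                if cfg.se_after_dense else None
            )
            if i < cfg.n_dense_blocks - 1:
                tb = TransitionBlock(c, cfg.compression, rng)
                self.transitions.append(tb)
                c = tb.out_channels
                length //= 2
                self._trace.append((f"transition{i + 1}", c, length))
                self.se_transition.append(
                    make_se_block(cfg.se_variant, c, cfg.reduction_ratio, rng)
                    if cfg.se_after_transition else None
                )
        self.se_head = (
            make_se_block(cfg.se_variant, c, cfg.reduction_ratio, rng)
            if cfg.se_before_head else None
        )
        self.head = PredictionBlock(c, cfg.n_outputs, rng,
                                    output_scale=cfg.output_scale)
        self.final_channels = c
        self.final_length = length

    # ------------------------------------------------------------------

    def forward(self, x: Tensor, record: dict[str, Tensor] | None = None) -> Tensor:
        """Run the network on ``x`` of shape (N, 1, W).

        If ``record`` is a dict it is filled with named stage activations
        (``stem``, ``dense1``.., ``transition1``.., ``pre_head``).
        """
        h = self.stem(x)
        if record is not None:
            record["stem"] = h
        for i, db in enumerate(self.dense_blocks):
            h = db(h)
            if record is not None:
                record[f"dense{i + 1}"] = h
            if self.se_dense[i] is not None:
                h = self.se_dense[i](h)
                if record is not None:
                    record[f"se_dense{i + 1}"] = h
            if i < len(self.transitions):
                h = self.transitions[i](h)
                if record is not None:
                    record[f"transition{i + 1}"] = h
                if self.se_transition[i] is not None:
                    h = self.se_transition[i](h)
                    if record is not None:
                        record[f"se_transition{i + 1}"] = h
        if self.se_head is not None:
            h = self.se_head(h)
            if record is not None:
                record["se_head"] = h
        if record is not None:
            record["pre_head"] = h
        return self.head(h)

    def predict(self, samples: np.ndarray) -> np.ndarray:
        """Landmark positions for beats ``samples`` of shape (N, W) or (W,)."""
        arr = np.asarray(samples, dtype=np.float64)
        single = arr.ndim == 1
        if single:
            arr = arr[None, :]
        was_training = self.training
        self.eval()
        with no_grad():
            out = self.forward(Tensor(arr[:, None, :])).data
        if was_training:
            self.train()
        return out[0] if single else out

    def stage_names(self) -> list[str]:
        names = ["stem"]
        for i in range(len(self.dense_blocks)):
            names.append(f"dense{i + 1}")
            if self.se_dense[i] is not None:
                names.append(f"se_dense{i + 1}")
            if i < len(self.transitions):
                names.append(f"transition{i + 1}")
                if self.se_transition[i] is not None:
                    names.append(f"se_transition{i + 1}")
        if self.se_head is not None:
            names.append("se_head")
        names.append("pre_head")
        return names

    def channel_trace(self) -> list[tuple[str, int, int]]:
        """Per-stage (name, channels, length) from the construction arithmetic."""
        return list(self._trace)

    def summary(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "stages": [
                {"name": n, "channels": c, "length": w}
                for n, c, w in self._trace
            ],
            "n_parameters": self.num_parameters(),
            "depth": self.config.depth,
        }


def build_dfenet(config: NetworkConfig | None = None,
                 seed: int | np.random.Generator = 0) -> DFENet:
    """Build a network from ``config`` with weights drawn from ``seed``."""
    if config is None:
        config = NetworkConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DFENet(config, rng)


def save_model(model: DFENet, path: str | Path) -> None:
    """Serialize config + weights to ``<path>.json`` / ``<path>.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(".json").write_text(json.dumps(model.config.to_dict(), indent=2))
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)


def load_model(path: str | Path) -> DFENet:
    path = Path(path)
    config = NetworkConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = build_dfenet(config, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[k] for k in data.files]
    model.load_state_arrays(arrays)
    model.eval()
    return model
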