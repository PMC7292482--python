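"""Architecture configuration for the dense feature-enhancement network."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

SE_VARIANTS = ("none", "cSE", "sSE", "scSE")
SE_POSITIONS = ("P1", "P2", "P3", "P4", "P5", "P6")

#: Positions at which an SE block follows each dense block.
_SE_AFTER_DENSE = {"P1", "P4", "P5", "P6"}
#: Positions at which an SE block follows each transition block.
_SE_AFTER_TRANSITION = {"P2", "P4", "P6"}
#: Positions with an SE block on the feature maps entering the prediction head.
_SE_BEFORE_HEAD = {"P3", "P5", "P6"}


@dataclass
class NetworkConfig:
    """Hyperparameters of the 1D dense network with squeeze-and-excitation.

    Defaults are the recommended operating point: growth rate ``g=12``,
    transition compression ``c=0.6``, SE reduction ratio ``r=8``, channel
    excitation (cSE) inserted after each dense block and before the
    prediction head (position P5).

    ``output_scale`` is a fixed gain on the prediction head: the head
    regresses fractional positions inside the padded analysis window and
    multiplies by the window length (250 samples) so predictions are in
    sample-index units.
    """

    n_dense_blocks: int = 3
    convs_per_dense_block: int = 4
    growth_rate: int = 12
    compression: float = 0.6
    init_channels: int | None = None  # defaults to 2 * growth_rate
    se_variant: str = "cSE"
    se_position: str = "P5"
    reduction_ratio: int = 8
    kernel_size: int = 3
    n_outputs: int = 3
    input_length: int = 250
    output_scale: float = 250.0

    def __post_init__(self):
        if self.init_channels is None:
            self.init_channels = 2 * self.growth_rate
        if self.n_dense_blocks != 3:
            raise ValueError("the architecture uses exactly 3 dense blocks")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must be in (0, 1]")
        if self.se_variant not in SE_VARIANTS:
            raise ValueError(f"se_variant must be one of {SE_VARIANTS}")
        if self.se_position not in SE_POSITIONS:
            raise ValueError(f"se_position must be one of {SE_POSITIONS}")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.growth_rate < 1 or self.convs_per_dense_block < 0:
            raise ValueError("invalid dense-block configuration")
        if self.n_outputs != 3:
            raise ValueError("the head predicts exactly 3 landmark positions")

    # SE placement queries -----------------------------------------------------

    @property
    def se_after_dense(self) -> bool:
        return self.se_variant != "none" and self.se_position in _SE_AFTER_DENSE

    @property
    def se_after_transition(self) -> bool:
        return self.se_variant != "none" and self.se_position in _SE_AFTER_TRANSITION

    @property
    def se_before_head(self) -> bool:
        return self.se_variant != "none" and self.se_position in _SE_BEFORE_HEAD

    @property
    def depth(self) -> int:
        """Convolution/FC layer count: stem + dense convs + transition convs + head."""
        return 1 + self.n_dense_blocks * self.convs_per_dense_block + 2 + 1

    # serialization -------------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
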