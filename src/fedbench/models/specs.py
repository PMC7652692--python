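"""Model and training configuration contracts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ModelSpec", "TrainingConfig", "FAMILIES"]

FAMILIES = ("mlp_image", "lstm_icu", "cnn_ecg", "linear_oracle")

# output dimension is fixed by the task for every family but the oracle
_FIXED_OUTPUTS = {"mlp_image": 10, "lstm_icu": 2, "cnn_ecg": 4}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract for one model family.

    Unset fields resolve to the family's defaults: MLP hidden width 128 with
    SGD lr 0.01; LSTM 16 hidden units, depth 2, dropout 0.3 with ADAM lr
    0.001; residual CNN 16 blocks of two convolutions (34 weighted layers
    with the stem and the classifier head) with ADAM lr 0.001. ``n_blocks``
    scales the CNN down for desk-size runs without changing the contract.
    """

    family: str
    n_features: int | None = None  # input dim (linear/mlp) or channels (lstm/cnn)
    n_classes: int | None = None
    hidden_units: int | None = None
    depth: int = 2
    dropout: float | None = None
    n_blocks: int | None = None
    channels: int = 16
    kernel_size: int = 7
    optimizer: str | None = None
    learning_rate: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        set_ = object.__setattr__
        if self.n_classes is None:
            if self.family == "linear_oracle":
                raise ValueError("linear_oracle requires n_classes")
            set_(self, "n_classes", _FIXED_OUTPUTS[self.family])
        elif self.family in _FIXED_OUTPUTS and self.n_classes != _FIXED_OUTPUTS[self.family]:
            raise ValueError(
                f"{self.family} has a fixed output dimension "
                f"{_FIXED_OUTPUTS[self.family]}, got {self.n_classes}"
            )
        if self.n_features is None:
            defaults = {"mlp_image": 784, "lstm_icu": 17, "cnn_ecg": 1}
            if self.family == "linear_oracle":
                raise ValueError("linear_oracle requires n_features")
            set_(self, "n_features", defaults[self.family])
        if self.hidden_units is None:
            set_(self, "hidden_units", {"mlp_image": 128, "lstm_icu": 16}.get(self.family, 0))
        if self.dropout is None:
            set_(self, "dropout", 0.3 if self.family == "lstm_icu" else 0.0)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_blocks is None:
            set_(self, "n_blocks", 16 if self.family == "cnn_ecg" else 0)
        if self.optimizer is None:
            set_(self, "optimizer", "sgd" if self.family in ("mlp_image", "linear_oracle") else "adam")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate is None:
            set_(self, "learning_rate", 0.01 if self.optimizer == "sgd" else 0.001)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def fingerprint(self) -> str:
        return (
            f"{self.family}/in{self.n_features}/out{self.n_classes}/"
            f"h{self.hidden_units}/d{self.depth}/b{self.n_blocks}/c{self.channels}"
        )

    @property
    def n_weighted_layers(self) -> int:
        """Layers carrying trainable weights (the depth the contract names)."""
        if self.family == "mlp_image":
            return 2
        if self.family == "linear_oracle":
            return 1
        if self.family == "lstm_icu":
            return self.depth + 1
        return 1 + 2 * self.n_blocks + 1  # stem + residual convs + classifier


@dataclass(frozen=True)
class TrainingConfig:
    """Local-training and round schedule.

    ``local_epochs`` (E) are passes over a client's shard per round;
    ``max_rounds`` (R) caps federation rounds; ``patience`` stops the run
    when the monitored metric has not improved for that many rounds
    (``None`` disables early stopping).
    """

    local_epochs: int = 1
    batch_size: int = 32
    max_rounds: int = 1
    patience: int | None = None
    monitor: str = "accuracy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be >= 1 or None")
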