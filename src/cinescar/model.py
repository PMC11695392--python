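"""The residual scar-classification CNN.

Architecture (U-Net-encoder style): an initial convolutional block
(conv 3x3, 64 kernels, batch norm, ReLU), three residual blocks with 128,
256 and 512 filters — each block runs two conv+BN+ReLU stages followed by
2x2 max pooling on the main path, while a 1x1 projection conv plus the same
pooling carries the block input across the skip connection; the two paths
are summed after pooling — then flatten, two fully connected blocks
(256 and 128 units, each dense + BN + dropout 0.2 + ReLU) and a final
one-unit dense layer whose sigmoid output is the probability of scar.
All kernels use He-uniform initialization.

The skip connection cannot be a pure identity because both the channel count
and the spatial size change inside a block; the 1x1 projection + pooling is
the minimal standard resolution of that shape mismatch.  Each residual block
halves both spatial dimensions exactly, so the input side must be divisible
by 8.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    input_side: int = 224
    base_filters: int = 64
    residual_filters: tuple[int, int, int] = (128, 256, 512)
    fc_units: tuple[int, int] = (256, 128)
    dropout: float = 0.2
    kernel_size: int = 3
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        n_pools = len(self.residual_filters)
        if self.input_side % (2**n_pools) != 0:
            raise ValueError(
                f"input_side must be divisible by {2**n_pools} "
                f"({n_pools} 2x2 poolings)"
            )


class ScarResNet:
    """Residual CNN wrapper exposing probability and logit forward passes."""

    def __init__(self, config: ModelConfig) -> None:
        config.validate()
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        dropout_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(1)[0]
        )
        c = config
        layers: list[nn.Layer] = [
            nn.Conv2d(c.in_channels, c.base_filters, c.kernel_size, rng, dtype),
            nn.BatchNorm(c.base_filters, dtype=dtype),
            nn.ReLU(),
        ]
        in_ch = c.base_filters
        for f in c.residual_filters:
            main = nn.Sequential(
                nn.Conv2d(in_ch, f, c.kernel_size, rng, dtype),
                nn.BatchNorm(f, dtype=dtype),
                nn.ReLU(),
                nn.Conv2d(f, f, c.kernel_size, rng, dtype),
                nn.BatchNorm(f, dtype=dtype),
                nn.ReLU(),
                nn.MaxPool2(),
            )
            skip = nn.Sequential(
                nn.Conv2d(in_ch, f, 1, rng, dtype),
                nn.MaxPool2(),
            )
            layers.append(nn.Residual(main, skip))
            in_ch = f
        side = c.input_side // (2 ** len(c.residual_filters))
        flat = in_ch * side * side
        layers.append(nn.Flatten())
        prev = flat
        for units in c.fc_units:
            layers.extend(
                [
                    nn.Dense(prev, units, rng, dtype),
                    nn.BatchNorm(units, dtype=dtype),
                    nn.Dropout(c.dropout, dropout_rng),
                    nn.ReLU(),
                ]
            )
            prev = units
        layers.append(nn.Dense(prev, 1, rng, dtype))
        self.net = nn.Sequential(*layers)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        return self.net.forward(x, training)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Scar probabilities in (0, 1), shape (N, 1)."""
        return nn.sigmoid(self.forward_logits(x, training))

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Evaluation-mode probabilities, shape (N,)."""
        x = np.asarray(x)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size], training=False).ravel())
        return np.concatenate(out) if out else np.empty(0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(np.asarray(grad, dtype=self.config.dtype))

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()

    # -- state --------------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.parameters()] + [
            b.copy() for b in self.net.buffers()
        ]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.net.parameters()
        buffers = self.net.buffers()
        if len(state) != len(params) + len(buffers):
            raise ValueError("state length does not match the model")
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        for b, v in zip(buffers, state[len(params):]):
            b[...] = v

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights, running stats and config JSON."""
        state = self.get_state()
        arrays = {f"arr_{i}": a for i, a in enumerate(state)}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(dataclasses.asdict(self.config)).encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScarResNet":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            cfg_dict["residual_filters"] = tuple(cfg_dict["residual_filters"])
            cfg_dict["fc_units"] = tuple(cfg_dict["fc_units"])
            config = ModelConfig(**cfg_dict)
            model = cls(config)
            n = len(model.get_state())
            model.set_state([data[f"arr_{i}"] for i in range(n)])
        return model

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.net.parameters()))


def build_model(config: ModelConfig) -> ScarResNet:
    """Construct the residual CNN for a given channel count and input side."""
    return ScarResNet(config)
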