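"""Architecture zoo for blood-pressure regression from PPG/ECG windows.

Seven families are constructed from a declarative :class:`ModelSpec`:

================== ========== =======================================================
family             setup      structure
================== ========== =======================================================
fc                 either     flatten - dense stack - linear head
lstm_stack         sequence   [bi]LSTM x3 - per-step linear head
wavenet            sequence   2 blocks x 4 dilated causal convs (dilation 1,2,4,8)
wavenet_lstm       sequence   wavenet trunk - LSTM stack - per-step linear head
resnet             direct     4 residual blocks (stride 2) - max pool - GAP - head
resnet_lstm_direct direct     4 residual blocks (stride 2) - LSTM stack - head
resnet_lstm_seq    sequence   4 residual blocks (stride 1, causal) - LSTM stack - head
================== ========== =======================================================

Direct-setup models map a ``(625, C)`` window to the two scalars (SBP, DBP).
Sequence-setup models map a ``(250, C)`` window to one output per timestep;
the final timestep is the prediction for the instant the window ends at.
Residual blocks follow the two-conv + batch-norm pattern with a skip
connection; sequence variants use causal padding, never pool, and keep
stride 1 so the output grid matches the input grid.

Output heads are single linear units with no activation.  Convolution
kernels default to 3; residual filters double per block from 64 to 512;
LSTM layers are 3 x 128 cells with the first bidirectional; WaveNet uses 32
filters per dilated layer (plain ReLU convolutions — no gated activations).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    BiConcat,
    Conv1d,
    Dense,
    Flatten,
    GlobalAvgPool1d,
    LastStep,
    LSTM,
    MaxPool1d,
    Module,
    ReLU,
    ResidualBlock,
    Reverse,
    Sequential,
)
from .nn import huber_loss  # re-exported: the training loss lives with the models

__all__ = [
    "ModelSpec",
    "Model",
    "build_model",
    "receptive_field",
    "huber_loss",
    "save_model",
    "load_model",
    "FAMILIES",
]

FAMILIES = (
    "fc",
    "lstm_stack",
    "wavenet",
    "wavenet_lstm",
    "resnet",
    "resnet_lstm_direct",
    "resnet_lstm_seq",
)
DIRECT_FAMILIES = ("fc", "resnet", "resnet_lstm_direct")
SEQUENCE_FAMILIES = ("fc", "lstm_stack", "wavenet", "wavenet_lstm", "resnet_lstm_seq")


@dataclass
class ModelSpec:
    """Declarative description of one architecture variant."""

    family: str = "resnet_lstm_direct"
    input_length: int = 625
    channels: int = 1
    fc_layers: tuple[int, ...] = (240, 180, 120)
    resnet_blocks: int = 4
    resnet_filters: tuple[int, ...] = (64, 128, 256, 512)
    kernel_size: int = 3
    wavenet_blocks: int = 2
    wavenet_layers_per_block: int = 4
    wavenet_filters: int = 32
    lstm_layers: int = 3
    lstm_width: int = 128
    first_lstm_bidirectional: bool = True
    setup: str = "direct"  # "direct" -> 2 scalar outputs; "sequence" -> per-step output

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("resnet", "resnet_lstm_direct") and self.setup != "direct":
            raise ValueError(f"{self.family} is a direct-setup family")
        if self.family in ("lstm_stack", "wavenet", "wavenet_lstm", "resnet_lstm_seq") and (
            self.setup != "sequence"
        ):
            raise ValueError(f"{self.family} is a sequence-setup family")
        if len(self.resnet_filters) != self.resnet_blocks:
            raise ValueError("resnet_filters must list one width per block")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        for key in ("fc_layers", "resnet_filters"):
            d[key] = tuple(d[key])
        return cls(**d)


class Model:
    """A built network plus its spec; callable on (N, T, C) batches."""

    def __init__(self, net: Module, spec: ModelSpec):
        self.net = net
        self.spec = spec
        # "scalars": output (N, K); "sequence": output (N, T)
        self.output_kind = "scalars" if spec.setup == "direct" or spec.family == "fc" else "sequence"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.net.forward(x, training=training)
        if self.output_kind == "sequence":
            out = out[..., 0]  # (N, T, 1) -> (N, T)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.output_kind == "sequence":
            grad = grad[..., None]
        return self.net.backward(grad)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode forward in batches."""
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict_point(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Scalar prediction per window: the direct head's outputs, or the
        final timestep of a sequence output."""
        out = self.predict(x, batch_size=batch_size)
        if self.output_kind == "sequence":
            return out[:, -1]
        return out[:, 0] if out.shape[1] == 1 else out

    def parameters(self):
        return self.net.parameters()

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def modules(self):
        yield from _iter_modules(self.net)


def _iter_modules(m: Module):
    yield m
    if isinstance(m, Sequential):
        for layer in m.layers:
            yield from _iter_modules(layer)
    elif isinstance(m, ResidualBlock):
        yield from _iter_modules(m.main)
        if m.shortcut is not None:
            yield from _iter_modules(m.shortcut)
    elif isinstance(m, BiConcat):
        yield from _iter_modules(m.fwd)
        yield from _iter_modules(m.bwd)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _lstm_stack(spec: ModelSpec, in_features: int, rng) -> tuple[list[Module], int]:
    """Three stacked LSTM layers, the first optionally bidirectional."""
    layers: list[Module] = []
    width = spec.lstm_width
    feat = in_features
    for i in range(spec.lstm_layers):
        if i == 0 and spec.first_lstm_bidirectional:
            layers.append(
                BiConcat(
                    LSTM(feat, width, rng),
                    Sequential(Reverse(), LSTM(feat, width, rng), Reverse()),
                )
            )
            feat = 2 * width
        else:
            layers.append(LSTM(feat, width, rng))
            feat = width
    return layers, feat


def _wavenet_trunk(spec: ModelSpec, rng) -> tuple[list[Module], int]:
    layers: list[Module] = []
    feat = spec.channels
    for _ in range(spec.wavenet_blocks):
        for layer_i in range(spec.wavenet_layers_per_block):
            layers.append(
                Conv1d(
                    feat,
                    spec.wavenet_filters,
                    spec.kernel_size,
                    rng,
                    dilation=2**layer_i,
                    padding="causal",
                )
            )
            layers.append(ReLU())
            feat = spec.wavenet_filters
    return layers, feat


def _resnet_trunk(spec: ModelSpec, rng, stride: int, padding: str) -> tuple[list[Module], int]:
    layers: list[Module] = []
    feat = spec.channels
    for width in spec.resnet_filters:
        layers.append(
            ResidualBlock(feat, width, spec.kernel_size, rng, stride=stride,
                          padding=padding)
        )
        feat = width
    return layers, feat


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct one architecture variant with seeded Glorot initialization."""
    rng = np.random.default_rng(seed)
    f = spec.family
    out_dim = 2 if spec.setup == "direct" else 1

    if f == "fc":
        layers: list[Module] = [Flatten()]
        feat = spec.input_length * spec.channels
        for width in spec.fc_layers:
            layers += [Dense(feat, width, rng), ReLU()]
            feat = width
        layers.append(Dense(feat, out_dim, rng))
        return Model(Sequential(*layers), spec)

    if f == "lstm_stack":
        layers, feat = _lstm_stack(spec, spec.channels, rng)
        layers.append(Dense(feat, 1, rng))
        return Model(Sequential(*layers), spec)

    if f == "wavenet":
        layers, feat = _wavenet_trunk(spec, rng)
        layers.append(Conv1d(feat, 1, 1, rng, padding="causal"))
        return Model(Sequential(*layers), spec)

    if f == "wavenet_lstm":
        layers, feat = _wavenet_trunk(spec, rng)
        lstm, feat = _lstm_stack(spec, feat, rng)
        layers += lstm
        layers.append(Dense(feat, 1, rng))
        return Model(Sequential(*layers), spec)

    if f == "resnet":
        layers, feat = _resnet_trunk(spec, rng, stride=2, padding="same")
        layers += [MaxPool1d(2), GlobalAvgPool1d(), Dense(feat, out_dim, rng)]
        return Model(Sequential(*layers), spec)

    if f == "resnet_lstm_direct":
        layers, feat = _resnet_trunk(spec, rng, stride=2, padding="same")
        lstm, feat = _lstm_stack(spec, feat, rng)
        layers += lstm
        layers += [LastStep(), Dense(feat, out_dim, rng)]
        return Model(Sequential(*layers), spec)

    if f == "resnet_lstm_seq":
        layers, feat = _resnet_trunk(spec, rng, stride=1, padding="causal")
        lstm, feat = _lstm_stack(spec, feat, rng)
        layers += lstm
        layers.append(Dense(feat, 1, rng))
        return Model(Sequential(*layers), spec)

    raise ValueError(f"unknown family {f!r}")


# ---------------------------------------------------------------------------
# Receptive field
# ---------------------------------------------------------------------------

def receptive_field(spec: ModelSpec) -> int:
    """Analytic receptive field (input samples per output sample) of the
    convolutional trunk of a conv-containing family.

    RF accumulates ``(kernel-1) * dilation * jump`` per convolution (and
    ``(pool-1) * jump`` per pooling stage), where ``jump`` is the product of
    the strides seen so far.  Families with no convolutions have no defined
    receptive field.
    """
    f = spec.family
    if f in ("fc", "lstm_stack"):
        raise ValueError(f"receptive field undefined for family {f!r}")
    rf, jump = 1, 1
    if f in ("wavenet", "wavenet_lstm"):
        for _ in range(spec.wavenet_blocks):
            for layer_i in range(spec.wavenet_layers_per_block):
                rf += (spec.kernel_size - 1) * (2**layer_i) * jump
        return rf
    stride = 1 if f == "resnet_lstm_seq" else 2
    for _ in spec.resnet_filters:
        rf += (spec.kernel_size - 1) * jump  # first conv of the block
        jump *= stride
        rf += (spec.kernel_size - 1) * jump  # second conv (stride 1)
    if f == "resnet":
        rf += 1 * jump  # max pool of width 2
        jump *= 2
    return rf


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: Model, path: str | Path) -> None:
    """Save parameters and batch-norm running statistics as ``.npz`` with a
    JSON spec sidecar."""
    path = Path(path)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    bn = [m for m in model.modules() if isinstance(m, BatchNorm1d)]
    for i, m in enumerate(bn):
        arrays[f"bn{i}_mean"] = m.running_mean
        arrays[f"bn{i}_var"] = m.running_var
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(model.spec.to_json())


def load_model(path: str | Path) -> Model:
    path = Path(path)
    spec = ModelSpec.from_json(path.with_suffix(".json").read_text())
    model = build_model(spec, seed=0)
    arrays = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.parameters()):
        p.value[...] = arrays[f"p{i}"]
    bn = [m for m in model.modules() if isinstance(m, BatchNorm1d)]
    for i, m in enumerate(bn):
        m.running_mean[...] = arrays[f"bn{i}_mean"]
        m.running_var[...] = arrays[f"bn{i}_var"]
    return model
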