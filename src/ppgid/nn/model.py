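"""The CNN+LSTM classifier: stem convolution, MBConv stack, LSTM head.

The feature extractor is a compact EfficientNet-style stack — a strided
stem convolution followed by inverted-residual blocks with squeeze-and-
excitation gating and Swish activations. Its final H' x W' x C' feature map
is read as a sequence of H' row vectors (each W' * C' long, row-major),
consumed by an LSTM whose final hidden state feeds a dense softmax head.

Two presets are provided: ``tiny`` (64-pixel input, 3 blocks, < 200k
parameters) for desk-scale training, and ``paper_scale``, which follows the
published B0-family block layout (224-pixel input, 7-stage stack) and is
meant for construction/inspection rather than CPU training.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    Activation,
    BatchNorm2d,
    Conv2d,
    Dense,
    Layer,
    LSTM,
    MBConv,
    Param,
    softmax,
)

__all__ = ["BlockSpec", "ModelConfig", "PpgNet", "build_model", "TINY", "PAPER_SCALE"]


@dataclass(frozen=True)
class BlockSpec:
    expansion: int
    out_channels: int
    stride: int
    se_reduction: int = 4

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


@dataclass(frozen=True)
class ModelConfig:
    input_side: int = 64
    in_channels: int = 1
    stem_channels: int = 8
    blocks: tuple[BlockSpec, ...] = ()
    lstm_hidden: int = 32
    n_classes: int = 40
    activation: str = "swish"  # hidden activation; softmax is always the output

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_side < 4 or self.lstm_hidden < 1:
            raise ValueError("invalid config")


def tiny_config(n_classes: int = 8, activation: str = "swish", input_side: int = 32) -> ModelConfig:
    return ModelConfig(
        input_side=input_side,
        stem_channels=8,
        blocks=(
            BlockSpec(expansion=2, out_channels=16, stride=2),
            BlockSpec(expansion=2, out_channels=16, stride=1),
            BlockSpec(expansion=2, out_channels=24, stride=1),
        ),
        lstm_hidden=32,
        n_classes=n_classes,
        activation=activation,
    )


def paper_scale_config(n_classes: int = 40, activation: str = "swish") -> ModelConfig:
    """B0-family layout: 7 stages of inverted-residual blocks after the stem."""
    stages = [
        # (expansion, out_channels, stride, repeats)
        (1, 16, 1, 1),
        (4, 32, 2, 2),
        (4, 48, 2, 2),
        (4, 96, 2, 3),
        (6, 112, 1, 3),
        (6, 192, 2, 4),
        (6, 320, 1, 1),
    ]
    blocks: list[BlockSpec] = []
    for t, ch, s, reps in stages:
        for r in range(reps):
            blocks.append(BlockSpec(expansion=t, out_channels=ch, stride=s if r == 0 else 1))
    return ModelConfig(
        input_side=224,
        stem_channels=32,
        blocks=tuple(blocks),
        lstm_hidden=128,
        n_classes=n_classes,
        activation=activation,
    )


TINY = "tiny"
PAPER_SCALE = "paper_scale"
_PRESETS = {TINY: tiny_config, PAPER_SCALE: paper_scale_config}


class PpgNet:
    """CNN feature extractor + LSTM sequence head + softmax classifier."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.classes: Optional[list[str]] = None  # label names, set at training time
        act = config.activation
        self.stem = Conv2d(config.in_channels, config.stem_channels, 3, stride=2, rng=rng, bias=False)
        self.stem_bn = BatchNorm2d(config.stem_channels)
        self.stem_act = Activation(act)
        self.blocks: list[MBConv] = []
        c = config.stem_channels
        side = -(-config.input_side // 2)  # ceil after stem stride 2
        for spec in config.blocks:
            self.blocks.append(
                MBConv(
                    c,
                    spec.out_channels,
                    expansion=spec.expansion,
                    stride=spec.stride,
                    se_reduction=spec.se_reduction,
                    activation=act,
                    rng=rng,
                )
            )
            c = spec.out_channels
            side = -(-side // spec.stride)
        self.feature_shape = (side, side, c)  # (H', W', C')
        self.lstm = LSTM(side * c, config.lstm_hidden, rng=rng)
        self.head = Dense(config.lstm_hidden, config.n_classes, rng=rng)

    # ---- parameters -------------------------------------------------
    @property
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for layer in self._layers():
            ps.extend(layer.params)
        return ps

    def _layers(self) -> list[Layer]:
        return [self.stem, self.stem_bn, self.stem_act, *self.blocks, self.lstm, self.head]

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params)

    def layer_count(self) -> int:
        """Number of weighted layers: each convolution, each SE module,
        the LSTM and the classification head count as one."""
        n = 1  # stem
        for spec in self.config.blocks:
            # expand conv (if any) + depthwise + SE + project
            n += (1 if spec.expansion != 1 else 0) + 1 + 1 + 1
        return n + 2  # + LSTM + classification head

    # ---- forward / backward ----------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[:, :, :, None]
        if x.shape[1] != self.config.input_side or x.shape[2] != self.config.input_side:
            raise ValueError(
                f"expected {self.config.input_side}x{self.config.input_side} input, "
                f"got {x.shape[1]}x{x.shape[2]}"
            )
        return x

    def extract_features(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Stem + block stack: (B, side, side, 1) -> (B, H', W', C')."""
        x = self._check_input(x)
        out = self.stem_act.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for blk in self.blocks:
            out = blk.forward(out, train)
        return out

    def sequence_and_classify(self, features: np.ndarray, train: bool = True) -> np.ndarray:
        """Rows of the feature map as time steps -> LSTM -> dense logits."""
        Bn, Hf, Wf, Cf = features.shape
        seq = features.reshape(Bn, Hf, Wf * Cf)  # row-major step vectors
        h = self.lstm.forward(seq, train)
        return self.head.forward(h, train)

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.sequence_and_classify(self.extract_features(x, train), train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward_logits(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        grad = self.lstm.backward(grad)
        Hf, Wf, Cf = self.feature_shape
        grad = grad.reshape(-1, Hf, Wf, Cf)
        for blk in reversed(self.blocks):
            grad = blk.backward(grad)
        grad = self.stem.backward(self.stem_bn.backward(self.stem_act.backward(grad)))

    # ---- state ------------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params]
        for layer in self._iter_bn():
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        for i, layer in enumerate(self._iter_bn()):
            layer.running_mean[...] = rest[2 * i]
            layer.running_var[...] = rest[2 * i + 1]

    def _iter_bn(self) -> list[BatchNorm2d]:
        bns = [self.stem_bn]
        for blk in self.blocks:
            bns.extend(l for l in blk.body.layers if isinstance(l, BatchNorm2d))
        return bns

    def save(self, path: str, seed: Optional[int] = None) -> None:
        """Checkpoint: weights + config + class names (+ seed) in one .npz."""
        cfg = dataclasses.asdict(self.config)
        cfg["blocks"] = [dataclasses.asdict(b) for b in self.config.blocks]
        meta = json.dumps({"config": cfg, "seed": seed, "classes": self.classes})
        arrays = {f"arr_{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "PpgNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        cfg["blocks"] = tuple(BlockSpec(**b) for b in cfg["blocks"])
        model = cls(ModelConfig(**cfg))
        model.classes = meta.get("classes")
        n = len(data.files) - 1
        model.set_state([data[f"arr_{i}"] for i in range(n)])
        return model


def build_model(
    config: Optional[ModelConfig] = None,
    preset: Optional[str] = None,
    n_classes: int = 40,
    seed: int = 0,
    activation: str = "swish",
) -> PpgNet:
    """Construct a model from an explicit config or a named preset."""
    if config is None:
        if preset not in _PRESETS:
            raise ValueError(f"preset must be one of {sorted(_PRESETS)}")
        config = _PRESETS[preset](n_classes=n_classes, activation=activation)
    rng = np.random.default_rng(seed)
    return PpgNet(config, rng=rng)
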