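"""Noise-map estimating U-Net.

A symmetric fully-convolutional encoder-decoder that maps one standardized
magnitude-image channel to one noise-map channel. The predicted map is
subtracted from the input to yield the denoised image (residual
formulation): the network never regresses the clean image directly.

Architecture (defaults): encoder depth 4, 64 initial 3x3 filters, feature
count doubling at each level (64, 128, 256, 512; 1024 at the bottleneck);
2x2 max pooling (stride 2) down, 2x2 transposed convolutions (stride 2)
up; pre-pool encoder features concatenated to the matching decoder level
(skip connections); each convolution followed by batch normalization then
ReLU, the ordering used by the reference U-Net implementations this
architecture derives from, and the more stable one under single-sample
batch statistics (``bn_after_activation=True`` switches to conv-ReLU-BN);
dropout (rate 0.5) at the bottleneck; a final linear 1x1 convolution so
predicted noise values may be negative.

Assumptions where the design was open: two convolutions per resolution
level, bottleneck-only dropout, concatenation as the skip merge.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import (
    DTYPE, Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, MaxPool2,
    ReLU, Sequential, iter_layers,
)

__all__ = ["UNetConfig", "UNet", "build_model", "predict_noise_map_std",
           "parameter_count", "save_model", "load_model"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    init_filters: int = 64
    kernel: int = 3
    dropout_rate: float = 0.5
    in_channels: int = 1
    out_channels: int = 1
    bn_after_activation: bool = False   # True: conv -> ReLU -> BN (literal text order)

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.init_filters < 1:
            raise ValueError("init_filters must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")

    @property
    def bottleneck_channels(self) -> int:
        return self.init_filters * 2 ** self.depth

    @property
    def size_multiple(self) -> int:
        """Input sides must divide this (2^depth) for even pooling."""
        return 2 ** self.depth


def _conv_unit(cin, cout, config, rng):
    conv = Conv2d(cin, cout, kernel=config.kernel, rng=rng)
    bn = BatchNorm2d(cout)
    if config.bn_after_activation:
        return [conv, ReLU(), bn]
    return [conv, bn, ReLU()]


def _block(cin, cout, config, rng):
    """Two convolution units per resolution level."""
    return Sequential(_conv_unit(cin, cout, config, rng)
                      + _conv_unit(cout, cout, config, rng))


class UNet:
    """U-Net with explicit forward/backward passes (sample at a time).

    Use :func:`build_model` to construct; :meth:`predict` for inference.
    """

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.init_filters
        self.enc = []
        self.pools = []
        ch = config.in_channels
        for level in range(config.depth):
            out = f * 2 ** level
            self.enc.append(_block(ch, out, config, rng))
            self.pools.append(MaxPool2())
            ch = out
        self.bottleneck = Sequential(
            _block(ch, 2 * ch, config, rng).layers + [Dropout(config.dropout_rate)])
        ch = 2 * ch
        self.ups = []
        self.dec = []
        for level in reversed(range(config.depth)):
            out = f * 2 ** level
            self.ups.append(ConvTranspose2d(ch, out, rng=rng))
            self.dec.append(_block(2 * out, out, config, rng))
            ch = out
        self.final = Conv2d(ch, config.out_channels, kernel=1, rng=rng)

    # ---- structure -------------------------------------------------
    def modules(self):
        return self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.final]

    def leaf_layers(self):
        return [l for m in self.modules() for l in iter_layers(m)]

    def make_optimizer(self, lr, beta1=0.9, beta2=0.99) -> Adam:
        return Adam(self.modules(), lr=lr, beta1=beta1, beta2=beta2)

    # ---- forward / backward ---------------------------------------
    def _check_shape(self, shape):
        m = self.config.size_multiple
        if shape[0] % m or shape[1] % m:
            raise ValueError(
                f"input size {shape[0]}x{shape[1]} is not divisible by 2^depth = {m}")

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """x: (in_channels, H, W) with H, W divisible by 2^depth."""
        self._check_shape(x.shape[1:])
        x = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training=training, rng=rng)
            skips.append(x)
            x = pool.forward(x, training=training, rng=rng)
        x = self.bottleneck.forward(x, training=training, rng=rng)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training=training, rng=rng)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = dec.forward(x, training=training, rng=rng)
        return self.final.forward(x, training=training, rng=rng)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.final.backward(np.ascontiguousarray(dy, dtype=DTYPE))
        dskips = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.dec),
                                   reversed(self._skip_channels)):
            dy = dec.backward(dy)
            dskips.append(dy[:c_skip])
            dy = up.backward(dy[c_skip:])
        dy = self.bottleneck.backward(dy)
        # dskips[i] belongs to encoder level i (the reversed loop above runs
        # decoder stages for levels 0, 1, ...); the encoder backward walks
        # levels depth-1 down to 0, so pair it with reversed(dskips).
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = block.backward(dy)

    # ---- inference -------------------------------------------------
    def predict(self, frame_std: np.ndarray) -> np.ndarray:
        """Predict a standardized noise map for a standardized 2D frame.

        Evaluation mode: dropout off, batch normalization using running
        statistics — deterministic.
        """
        frame_std = np.asarray(frame_std)
        if frame_std.ndim != 2:
            raise ValueError("predict expects a single 2D frame")
        out = self.forward(frame_std[None], training=False)
        return out[0].astype(np.float64)

    # ---- state -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.leaf_layers()):
            for name, arr in {**layer.params(), **layer.buffers()}.items():
                state[f"{i}.{name}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.leaf_layers()):
            for name, arr in {**layer.params(), **layer.buffers()}.items():
                arr[...] = state[f"{i}.{name}"]


def build_model(config: UNetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(config or UNetConfig(), seed=seed)


def predict_noise_map_std(model: UNet, frame_std: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`UNet.predict`."""
    return model.predict(frame_std)


def parameter_count(model: UNet) -> int:
    """Number of trainable parameters (a pure function of the config)."""
    return sum(arr.size for layer in model.leaf_layers()
               for arr in layer.params().values())


def save_model(model: UNet, path) -> None:
    """Checkpoint as .npz with the config embedded (self-describing)."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_model(path) -> UNet:
    with np.load(path) as data:
        cfg = UNetConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = UNet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
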