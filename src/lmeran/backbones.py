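"""Pluggable image backbones producing a grid of patch feature vectors.

Three backbones are registered:

``densenet121``
    The densely connected 121-layer network (4 dense blocks of 6/12/24/16
    layers, growth rate 32, overall stride 32), yielding a 14x14 grid of
    depth-1024 patch vectors on 448x448 input.  Weights are He-initialised at
    construction; trained weights can be restored from a checkpoint.  This
    backbone is a fixed (non-trainable) feature extractor.
``tiny``
    A 3-block strided convolutional network for desk-scale experiments:
    depth 32, 7x7 grid on 56x56 input.  Fully differentiable and trainable.
``stub``
    Emits a constant feature grid regardless of input; used to pin down
    contracts in tests.

Every backbone maps a batch of images (B, H, W) or (B, C, H, W) to a
``Tensor`` of shape (B, h*w, d) — patch vectors in row-major grid order.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, _im2col

__all__ = ["create_backbone", "register_backbone", "available_backbones",
           "TinyConvBackbone", "DenseNet121Backbone", "StubBackbone"]

_REGISTRY: dict = {}


def register_backbone(name: str, factory) -> None:
    _REGISTRY[name] = factory


def available_backbones() -> list:
    return sorted(_REGISTRY)


def create_backbone(name: str, rng: np.random.Generator | None = None, **kwargs):
    if name not in _REGISTRY:
        raise ValueError(f"unknown backbone {name!r}; available: {available_backbones()}")
    if rng is None:
        rng = np.random.default_rng(0)
    return _REGISTRY[name](rng, **kwargs)


def _as_nchw(images: np.ndarray, channels: int) -> np.ndarray:
    x = np.asarray(images)
    if x.dtype != np.float32:
        x = x.astype(np.float64, copy=False)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:  # (B, H, W) -> replicate channel
        x = np.repeat(x[:, None], channels, axis=1)
    elif x.shape[1] != channels:
        if x.shape[1] == 1:
            x = np.repeat(x, channels, axis=1)
        else:
            raise ValueError(f"expected {channels} channels, got {x.shape[1]}")
    return x


def _he(rng, *shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class TinyConvBackbone:
    """Three stride-2 conv+relu blocks: 56x56x1 -> 7x7x32 patch grid."""

    name = "tiny"
    d = 32
    trainable = True
    channels = 1

    _widths = (1, 8, 16, 32)

    def __init__(self, rng: np.random.Generator):
        self.weights = []
        self.biases = []
        for cin, cout in zip(self._widths[:-1], self._widths[1:]):
            w = Tensor(_he(rng, cout, cin, 3, 3, fan_in=cin * 9), requires_grad=True)
            b = Tensor(np.zeros(cout), requires_grad=True)
            self.weights.append(w)
            self.biases.append(b)

    def grid_shape(self, input_size: int) -> tuple:
        s = input_size
        for _ in self.weights:
            s = (s + 1) // 2
        return s, s

    def params(self) -> list:
        return [*self.weights, *self.biases]

    def forward(self, images: np.ndarray) -> Tensor:
        x = Tensor(_as_nchw(images, self.channels))
        for w, b in zip(self.weights, self.biases):
            x = conv2d(x, w, b, stride=2, padding=1).relu()
        n, c, h, w_ = x.shape
        return x.reshape(n, c, h * w_).transpose(0, 2, 1)  # (B, h*w, d)

    def state_dict(self) -> dict:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"conv{i}.weight"] = w.data
            out[f"conv{i}.bias"] = b.data
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            w.data = np.asarray(state[f"conv{i}.weight"], dtype=np.float64)
            b.data = np.asarray(state[f"conv{i}.bias"], dtype=np.float64)


class StubBackbone:
    """Constant-output backbone: every patch vector equals ``value``."""

    name = "stub"
    trainable = False
    channels = 1

    def __init__(self, rng=None, h: int = 2, w: int = 2, d: int = 4,
                 value: float = 1.0):
        self.h, self.w, self.d = h, w, d
        self.value = value

    def grid_shape(self, input_size: int) -> tuple:
        return self.h, self.w

    def params(self) -> list:
        return []

    def forward(self, images: np.ndarray) -> Tensor:
        x = np.asarray(images)
        batch = 1 if x.ndim == 2 else x.shape[0]
        return Tensor(np.full((batch, self.h * self.w, self.d), self.value))


def _conv_np(x, w, stride=1, pad=0):
    cout = w.shape[0]
    cols, ho, wo = _im2col(x, w.shape[2], w.shape[3], stride, pad)
    y = cols @ w.reshape(cout, -1).T
    return y.reshape(x.shape[0], ho, wo, cout).transpose(0, 3, 1, 2)


class DenseNet121Backbone:
    """Densely connected 121-layer feature extractor (inference only).

    Dense layers are BN-relu-conv(1x1, 4k)-BN-relu-conv(3x3, k) with growth
    k = 32 and feature concatenation; transitions halve channels (1x1 conv)
    and spatial size (2x2 average pool).  Overall stride 32, output depth
    1024, so a 448x448 image yields a 14x14 grid.  Batch-norm statistics
    default to (0, 1) until trained parameters are loaded.
    """

    name = "densenet121"
    d = 1024
    trainable = False
    channels = 3
    growth = 32
    block_config = (6, 12, 24, 16)

    def __init__(self, rng: np.random.Generator):
        self.params_np: dict = {}
        p = self.params_np
        p["conv0"] = _he(rng, 64, 3, 7, 7, fan_in=3 * 49).astype(np.float32)
        c = 64
        for bi, nlayers in enumerate(self.block_config):
            for li in range(nlayers):
                cin = c + li * self.growth
                p[f"b{bi}l{li}.conv1"] = _he(
                    rng, 4 * self.growth, cin, 1, 1, fan_in=cin
                ).astype(np.float32)
                p[f"b{bi}l{li}.conv2"] = _he(
                    rng, self.growth, 4 * self.growth, 3, 3, fan_in=4 * self.growth * 9
                ).astype(np.float32)
            c += nlayers * self.growth
            if bi < len(self.block_config) - 1:
                p[f"t{bi}.conv"] = _he(rng, c // 2, c, 1, 1, fan_in=c).astype(np.float32)
                c //= 2
        assert c == self.d

    def grid_shape(self, input_size: int) -> tuple:
        if input_size % 32 != 0:
            raise ValueError("densenet121 requires the input size to be a multiple of 32")
        return input_size // 32, input_size // 32

    def params(self) -> list:
        return []  # fixed feature extractor

    @staticmethod
    def _bn_relu(x):
        # statistics (0, 1) until trained parameters are supplied
        return np.maximum(x, 0.0)

    def forward(self, images: np.ndarray) -> Tensor:
        p = self.params_np
        x = _as_nchw(images, 3).astype(np.float32)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("image size incompatible with stride-32 backbone")
        x = _conv_np(x, p["conv0"], stride=2, pad=3)
        x = self._bn_relu(x)
        x = self._maxpool3s2(x)
        for bi, nlayers in enumerate(self.block_config):
            feats = [x]
            for li in range(nlayers):
                h = np.concatenate(feats, axis=1)
                h = self._bn_relu(h)
                h = _conv_np(h, p[f"b{bi}l{li}.conv1"])
                h = self._bn_relu(h)
                h = _conv_np(h, p[f"b{bi}l{li}.conv2"], pad=1)
                feats.append(h)
            x = np.concatenate(feats, axis=1)
            if bi < len(self.block_config) - 1:
                x = self._bn_relu(x)
                x = _conv_np(x, p[f"t{bi}.conv"])
                x = self._avgpool2(x)
        x = self._bn_relu(x)
        n, c, h, w = x.shape
        return Tensor(x.reshape(n, c, h * w).transpose(0, 2, 1).astype(np.float64))

    @staticmethod
    def _maxpool3s2(x):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        return win[:, :, ::2, ::2].max(axis=(-1, -2))

    @staticmethod
    def _avgpool2(x):
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def state_dict(self) -> dict:
        return dict(self.params_np)

    def load_state_dict(self, state: dict) -> None:
        for k in self.params_np:
            self.params_np[k] = np.asarray(state[k], dtype=np.float32)


register_backbone("tiny", lambda rng, **kw: TinyConvBackbone(rng, **kw))
register_backbone("stub", lambda rng, **kw: StubBackbone(rng, **kw))
register_backbone("densenet121", lambda rng, **kw: DenseNet121Backbone(rng, **kw))
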