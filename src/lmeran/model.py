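"""Core model: label/state fusion, label-specific residual attention, heads.

The classifier couples two sources of information per disease label i:

* a global image descriptor ``g``, the average of all backbone patch
  vectors (average pooling over the feature grid), and
* a label-specific residual ``r_i``, the output token of a multi-head
  self-attention stack run over the joint sequence of patch vectors and
  fused label tokens ``c_i = l_i + s_i`` (label embedding plus the
  embedding of its state: unknown / negative / positive).

The per-label feature is ``z_i = g + lam * r_i`` and the prediction is
``sigmoid(w_i . z_i + b_i)``.  Because label tokens attend to each other as
well as to the image, revealing the state of one label can move the
predictions of the others — the mechanism the label-mask training strategy
exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, dropout
from .backbones import create_backbone
from .config import ModelConfig

__all__ = [
    "STATES", "STATE_NAMES", "encode_states",
    "fuse_label_state", "global_pool", "build_token_set",
    "AttentionLayerParams", "attention_layer", "attention_stack",
    "combine_residual", "classify", "LMeRAN",
    "save_checkpoint", "load_checkpoint",
]

STATES = {"unknown": 0, "negative": 1, "positive": 2}
STATE_NAMES = ("unknown", "negative", "positive")


def encode_states(states, n: int) -> np.ndarray:
    """Convert state strings/codes to an integer array, validating values."""
    arr = np.asarray(states)
    if arr.ndim == 1:
        arr = arr[None]
    if arr.shape[-1] != n:
        raise ValueError(f"state list has length {arr.shape[-1]}, expected {n}")
    if arr.dtype.kind in "US":
        out = np.empty(arr.shape, dtype=np.int64)
        for name, code in STATES.items():
            out[arr == name] = code
        bad = ~np.isin(arr, list(STATES))
        if bad.any():
            raise ValueError(f"unknown state string {arr[bad][0]!r}")
        return out
    out = arr.astype(np.int64)
    if ((out < 0) | (out > 2)).any():
        raise ValueError("state codes must be 0 (unknown), 1 (negative) or 2 (positive)")
    return out


def fuse_label_state(label_emb: Tensor, state_emb: Tensor) -> Tensor:
    """Fused label token c = l + s (elementwise)."""
    if label_emb.shape[-1] != state_emb.shape[-1]:
        raise ValueError("label and state embedding depths differ")
    return label_emb + state_emb


def global_pool(fmap: Tensor) -> Tensor:
    """Mean of the patch vectors: (..., h*w, d) -> (..., d)."""
    if fmap.shape[-2] == 0:
        raise ValueError("empty feature map")
    return fmap.mean(axis=-2)


def build_token_set(fmap: Tensor, fused_labels: Tensor) -> Tensor:
    """Concatenate patch tokens then label tokens: M = h*w + n."""
    if fused_labels.shape[-2] == 0:
        raise ValueError("empty label token list")
    if fmap.shape[-1] != fused_labels.shape[-1]:
        raise ValueError("token depth mismatch between patches and labels")
    return concat([fmap, fused_labels], axis=-2)


@dataclass
class AttentionLayerParams:
    """Per-layer attention weights (layer-local, never shared).

    wq, wk, wv have shape (p, d, d/p): one query/key/value map per head;
    wo has shape (d, d) and mixes the concatenated heads back to depth d.
    Optional pre-norm transformer-block parameters (layer norm scales and a
    two-layer feed-forward) are populated only in ``transformer_block`` mode.
    """

    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    ln1: tuple | None = None    # (gamma, beta)
    ln2: tuple | None = None
    ffn: tuple | None = None    # (w1, b1, w2, b2)

    @classmethod
    def init(cls, d: int, p: int, rng: np.random.Generator,
             transformer_block: bool = False) -> "AttentionLayerParams":
        if d % p != 0:
            raise ValueError(f"head count {p} does not divide depth {d}")
        dh = d // p
        scale = 1.0 / np.sqrt(d)

        def w(*shape):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        params = cls(wq=w(p, d, dh), wk=w(p, d, dh), wv=w(p, d, dh), wo=w(d, d))
        if transformer_block:
            params.ln1 = (Tensor(np.ones(d), requires_grad=True),
                          Tensor(np.zeros(d), requires_grad=True))
            params.ln2 = (Tensor(np.ones(d), requires_grad=True),
                          Tensor(np.zeros(d), requires_grad=True))
            params.ffn = (w(d, 2 * d), Tensor(np.zeros(2 * d), requires_grad=True),
                          w(2 * d, d), Tensor(np.zeros(d), requires_grad=True))
        return params

    def tensors(self) -> list:
        out = [self.wq, self.wk, self.wv, self.wo]
        for group in (self.ln1, self.ln2, self.ffn):
            if group is not None:
                out.extend(group)
        return out

    @property
    def heads(self) -> int:
        return self.wq.shape[0]


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


def _attention_core(tokens: Tensor, params: AttentionLayerParams,
                    dropout_rate: float, rng, training: bool,
                    scale_mode: str):
    b, m, d = tokens.shape
    p = params.heads
    dh = d // p
    x = tokens.reshape(b, 1, m, d)
    q = x @ params.wq                       # (b, p, m, dh)
    k = x @ params.wk
    v = x @ params.wv
    scale = 1.0 / d if scale_mode == "literal_d" else 1.0 / np.sqrt(dh)
    scores = (q @ k.transpose(0, 1, 3, 2)) * scale
    if not np.isfinite(scores.data).all():
        raise FloatingPointError("non-finite attention scores")
    alpha = scores.softmax(axis=-1)         # (b, p, m, m)
    alpha_d = dropout(alpha, dropout_rate, rng, training)
    heads = alpha_d @ v                     # (b, p, m, dh)
    merged = heads.transpose(0, 2, 1, 3).reshape(b, m, p * dh)
    out = merged @ params.wo
    out = dropout(out, dropout_rate, rng, training)
    return out, alpha


def attention_layer(tokens: Tensor, params: AttentionLayerParams,
                    dropout_rate: float = 0.0,
                    rng: np.random.Generator | None = None,
                    training: bool = False,
                    scale_mode: str = "sqrt_head",
                    transformer_block: bool = False):
    """One multi-head self-attention layer over the joint token set.

    Returns ``(updated_tokens, attention)`` where ``attention`` has shape
    (batch, heads, M, M) and each row sums to one.  The default layer is the
    bare attention map with dropout on weights and output; in
    ``transformer_block`` mode it is wrapped as a pre-norm block with a
    feed-forward sublayer and skip connections.
    """
    if tokens.ndim == 2:
        tokens = tokens.reshape(1, *tokens.shape)
    d = tokens.shape[-1]
    if d % params.heads != 0:
        raise ValueError("head count does not divide token depth")
    if training and dropout_rate > 0.0 and rng is None:
        raise ValueError("training-mode dropout needs a random generator")
    if not transformer_block:
        return _attention_core(tokens, params, dropout_rate, rng, training,
                               scale_mode)
    attn_in = _layer_norm(tokens, *params.ln1)
    attn_out, alpha = _attention_core(attn_in, params, dropout_rate, rng,
                                      training, scale_mode)
    x = tokens + attn_out
    h = _layer_norm(x, *params.ln2)
    w1, b1, w2, b2 = params.ffn
    h = ((h @ w1 + b1).relu()) @ w2 + b2
    return x + dropout(h, dropout_rate, rng, training), alpha


def attention_stack(tokens: Tensor, layers: list,
                    dropout_rate: float = 0.0,
                    rng: np.random.Generator | None = None,
                    training: bool = False,
                    scale_mode: str = "sqrt_head",
                    transformer_block: bool = False):
    """Apply attention layers sequentially; collect per-layer attention maps."""
    if not layers:
        raise ValueError("attention stack needs at least one layer")
    alphas = []
    for params in layers:
        tokens, alpha = attention_layer(
            tokens, params, dropout_rate=dropout_rate, rng=rng,
            training=training, scale_mode=scale_mode,
            transformer_block=transformer_block)
        alphas.append(alpha)
    return tokens, alphas


def combine_residual(g: Tensor, r: Tensor, lam: float) -> Tensor:
    """Per-label feature z_i = g + lam * r_i."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if g.shape[-1] != r.shape[-1]:
        raise ValueError("depth mismatch between global and residual features")
    if g.ndim == r.ndim - 1:
        g = g.reshape(*g.shape[:-1], 1, g.shape[-1])
    return g + lam * r

def classify(z: Tensor, weights: Tensor, bias: Tensor) -> Tensor:
    """Per-label probability sigmoid(w_i . z_i + b_i); z is (..., n, d)."""
    if z.shape[-1] != weights.shape[-1]:
        raise ValueError("classifier depth mismatch")
    logits = (z * weights).sum(axis=-1) + bias
    return logits.sigmoid()


class LMeRAN:
    """Label-masking residual attention classifier.

    Parameters
    ----------
    config
        Architecture configuration; ``config.labels`` fixes the ordered
        vocabulary and the number of label tokens.
    rng
        Generator (or seed) used for weight initialisation.
    """

    def __init__(self, config: ModelConfig, rng=0, backbone=None):
        if config.n < 1:
            raise ValueError("model needs at least one label")
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        self.config = config
        self.labels = list(config.labels)
        self.backbone = backbone if backbone is not None else create_backbone(
            config.backbone, rng)
        self.d = self.backbone.d
        if self.d % config.heads != 0:
            raise ValueError(f"heads={config.heads} does not divide depth d={self.d}")
        self.h, self.w = self.backbone.grid_shape(config.input_size)
        n, d = config.n, self.d
        self.label_emb = Tensor(rng.normal(0, 1 / np.sqrt(d), (n, d)),
                                requires_grad=True)
        self.state_emb = Tensor(rng.normal(0, 1 / np.sqrt(d), (3, d)),
                                requires_grad=True)
        self.layers = [
            AttentionLayerParams.init(d, config.heads, rng,
                                      config.transformer_block)
            for _ in range(config.layers)
        ]
        self.cls_w = Tensor(rng.normal(0, 1 / np.sqrt(d), (n, d)),
                            requires_grad=True)
        self.cls_b = Tensor(np.zeros(n), requires_grad=True)

    # ------------------------------------------------------------------ parts
    @property
    def n(self) -> int:
        return len(self.labels)

    def astype(self, dtype) -> "LMeRAN":
        """Cast every trainable parameter in place (float32 speeds training)."""
        for t in self.params():
            t.data = t.data.astype(dtype)
        return self

    @property
    def dtype(self):
        return self.label_emb.data.dtype

    def params(self) -> list:
        out = list(self.backbone.params())
        out += [self.label_emb, self.state_emb, self.cls_w, self.cls_b]
        for layer in self.layers:
            out += layer.tensors()
        return out

    def extract_features(self, images: np.ndarray) -> Tensor:
        """Backbone patch features (B, h*w, d); deterministic in eval mode."""
        fmap = self.backbone.forward(images)
        if fmap.shape[-2] != self.h * self.w:
            raise ValueError(
                f"backbone produced {fmap.shape[-2]} patches, expected "
                f"{self.h}x{self.w} for input size {self.config.input_size}")
        return fmap

    def fused_label_tokens(self, states: np.ndarray) -> Tensor:
        """(B, n) state codes -> (B, n, d) fused tokens c_i = l_i + s_i."""
        codes = encode_states(states, self.n)
        return fuse_label_state(self.label_emb, self.state_emb[codes])

    # ---------------------------------------------------------------- forward
    def forward(self, images: np.ndarray, states,
                training: bool = False,
                rng: np.random.Generator | None = None,
                return_attention: bool = False):
        """Predict per-label probabilities.

        Returns the probability Tensor (B, n), or ``(probs, alphas)`` when
        ``return_attention`` is set, ``alphas`` being one (B, p, M, M) array
        per layer.
        """
        fmap = self.extract_features(images)
        g = global_pool(fmap)
        fused = self.fused_label_tokens(states)
        if fused.shape[0] == 1 and fmap.shape[0] > 1:
            fused = fused + Tensor(np.zeros((fmap.shape[0], 1, 1)))
        tokens = build_token_set(fmap, fused)
        out_tokens, alphas = attention_stack(
            tokens, self.layers,
            dropout_rate=self.config.dropout, rng=rng, training=training,
            scale_mode=self.config.attention_scale,
            transformer_block=self.config.transformer_block)
        r = out_tokens[:, self.h * self.w:, :]   # residual label tokens
        z = combine_residual(g, r, self.config.lam)
        probs = classify(z, self.cls_w, self.cls_b)
        if return_attention:
            return probs, [a.data for a in alphas]
        return probs


# ------------------------------------------------------------------ serialise
def save_checkpoint(model: LMeRAN, path) -> None:
    """Write a single-archive checkpoint (weights + config + vocabulary)."""
    from dataclasses import asdict

    arrays = {
        "label_emb": model.label_emb.data,
        "state_emb": model.state_emb.data,
        "cls_w": model.cls_w.data,
        "cls_b": model.cls_b.data,
    }
    for i, layer in enumerate(model.layers):
        arrays[f"layer{i}.wq"] = layer.wq.data
        arrays[f"layer{i}.wk"] = layer.wk.data
        arrays[f"layer{i}.wv"] = layer.wv.data
        arrays[f"layer{i}.wo"] = layer.wo.data
        if layer.ffn is not None:
            for name, t in zip(("ln1_g", "ln1_b"), layer.ln1):
                arrays[f"layer{i}.{name}"] = t.data
            for name, t in zip(("ln2_g", "ln2_b"), layer.ln2):
                arrays[f"layer{i}.{name}"] = t.data
            for name, t in zip(("ffn_w1", "ffn_b1", "ffn_w2", "ffn_b2"), layer.ffn):
                arrays[f"layer{i}.{name}"] = t.data
    if hasattr(model.backbone, "state_dict"):
        for k, v in model.backbone.state_dict().items():
            arrays[f"backbone.{k}"] = v
    meta = json.dumps(asdict(model.config))
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> LMeRAN:
    with np.load(path) as archive:
        arrays = {k: archive[k] for k in archive.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    config = ModelConfig(**meta)
    model = LMeRAN(config, rng=0)
    model.label_emb.data = arrays["label_emb"]
    model.state_emb.data = arrays["state_emb"]
    model.cls_w.data = arrays["cls_w"]
    model.cls_b.data = arrays["cls_b"]
    for i, layer in enumerate(model.layers):
        layer.wq.data = arrays[f"layer{i}.wq"]
        layer.wk.data = arrays[f"layer{i}.wk"]
        layer.wv.data = arrays[f"layer{i}.wv"]
        layer.wo.data = arrays[f"layer{i}.wo"]
        if layer.ffn is not None:
            layer.ln1[0].data = arrays[f"layer{i}.ln1_g"]
            layer.ln1[1].data = arrays[f"layer{i}.ln1_b"]
            layer.ln2[0].data = arrays[f"layer{i}.ln2_g"]
            layer.ln2[1].data = arrays[f"layer{i}.ln2_b"]
            for name, t in zip(("ffn_w1", "ffn_b1", "ffn_w2", "ffn_b2"), layer.ffn):
                t.data = arrays[f"layer{i}.{name}"]
    backbone_state = {k[len("backbone."):]: v for k, v in arrays.items()
                      if k.startswith("backbone.")}
    if backbone_state and hasattr(model.backbone, "load_state_dict"):
        model.backbone.load_state_dict(backbone_state)
    return model
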