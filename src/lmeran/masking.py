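"""Label-mask training primitives: mask sampling, state assignment, loss.

During training a random subset of the n labels is hidden from the model:
the number of masked labels u is drawn uniformly from the integers
{ceil(R*n), ..., n} (lower-bound ratio R, default 0.25) and the identity of
the masked labels is a uniform random u-subset, redrawn fresh for every
sample in every epoch.  Masked labels receive the "unknown" state; revealed
labels carry their ground-truth state ("positive"/"negative").  The loss is
binary cross-entropy restricted to the masked labels only, so the model is
trained to infer hidden labels from the image plus the revealed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .model import STATES

__all__ = ["MaskSpec", "sample_mask", "assign_states", "masked_bce_loss",
           "PROB_EPS"]

PROB_EPS = 1e-7  # probabilities clipped to [eps, 1-eps] before the log


@dataclass(frozen=True)
class MaskSpec:
    """The masked/known partition of the n labels for one sample."""

    n: int
    masked: frozenset

    def __post_init__(self):
        if not all(0 <= i < self.n for i in self.masked):
            raise ValueError("masked index out of range")

    @property
    def u(self) -> int:
        return len(self.masked)

    @property
    def known(self) -> frozenset:
        return frozenset(range(self.n)) - self.masked

    def bool_mask(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        out[list(self.masked)] = True
        return out


def sample_mask(n: int, R: float = 0.25,
                rng: np.random.Generator | None = None) -> MaskSpec:
    """Draw a fresh mask: u ~ Uniform{ceil(R*n), ..., n}, then a u-subset."""
    if n < 1:
        raise ValueError("need at least one label")
    if not 0.0 <= R <= 1.0:
        raise ValueError("mask ratio lower bound must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    lo = int(np.ceil(R * n))
    u = int(rng.integers(lo, n + 1))
    masked = rng.choice(n, size=u, replace=False) if u else np.empty(0, int)
    return MaskSpec(n=n, masked=frozenset(int(i) for i in masked))


def assign_states(y: np.ndarray, mask: MaskSpec) -> np.ndarray:
    """Per-label state codes: masked -> unknown, else positive/negative by y."""
    y = np.asarray(y)
    if y.shape[-1] != mask.n:
        raise ValueError("target length does not match mask")
    states = np.where(y > 0, STATES["positive"], STATES["negative"])
    states[..., list(mask.masked)] = STATES["unknown"]
    return states


def masked_bce_loss(probs, y, mask) -> Tensor:
    """Binary cross-entropy over masked labels only.

    ``probs`` is a (B, n) Tensor (or array), ``y`` the (B, n) binary targets
    and ``mask`` a MaskSpec, a list of MaskSpecs (one per sample) or a
    boolean (B, n) array marking masked entries.  Per sample the masked-label
    BCE terms are averaged, then averaged over the batch; known-label
    predictions contribute exactly zero (their gradient vanishes
    identically).
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    if probs.ndim == 1:
        probs = probs.reshape(1, -1)
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if isinstance(mask, MaskSpec):
        mask_arr = np.broadcast_to(mask.bool_mask(), probs.shape)
    elif isinstance(mask, (list, tuple)):
        mask_arr = np.stack([m.bool_mask() for m in mask])
    else:
        mask_arr = np.atleast_2d(np.asarray(mask, dtype=bool))
    if mask_arr.shape != probs.shape or y.shape != probs.shape:
        raise ValueError("shape mismatch between predictions, targets and mask")
    counts = mask_arr.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("every sample must have at least one masked label")
    p = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
    terms = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())
    weights = mask_arr / counts[:, None] / mask_arr.shape[0]
    return (terms * Tensor(weights)).sum()
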