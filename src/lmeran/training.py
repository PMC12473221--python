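"""Training loop (Adam/SGD on the masked-label objective) and inference.

One optimisation step processes a mini-batch by drawing a fresh mask per
sample, assigning label states from the ground truth, running the forward
pass in train mode and back-propagating the masked-only binary
cross-entropy.  All randomness (mask draws, batch shuffling, dropout) flows
from one seeded generator, so identical seeds and data give identical loss
traces on one machine.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import TrainConfig
from .masking import assign_states, masked_bce_loss, sample_mask
from .model import LMeRAN, STATES, encode_states, save_checkpoint

__all__ = ["Adam", "SGD", "train", "predict"]


class SGD:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def _make_optimizer(name: str, params, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")


def train(model: LMeRAN, dataset, config: TrainConfig,
          out_dir=None, log=None, augment=None):
    """Fit ``model`` on ``dataset`` (a sequence of (image, target) pairs).

    ``augment``, if given, is applied per image per step as
    ``augment(image, rng)`` (e.g. :func:`lmeran.data.augment` for random
    crop/scale and horizontal flip).  Returns a dict with the per-step loss
    trace, per-epoch means, and the path of the last checkpoint if
    ``out_dir`` was given.  Raises ``FloatingPointError`` with a diagnostic
    if the loss goes non-finite.
    """
    rng = np.random.default_rng(config.seed)
    images = np.stack([np.asarray(img, dtype=model.dtype) for img, _ in dataset])
    targets = np.stack([np.asarray(y) for _, y in dataset]).astype(np.int64)
    n_samples, n = targets.shape
    if n != model.n:
        raise ValueError(f"dataset has {n} labels, model expects {model.n}")
    optimizer = _make_optimizer(config.optimizer, model.params(),
                                config.learning_rate)
    step_losses: list = []
    epoch_losses: list = []
    ckpt_path = None
    for epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        epoch_sum, epoch_steps = 0.0, 0
        for start in range(0, n_samples, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_x = images[idx]
            if augment is not None:
                batch_x = np.stack([augment(img, rng) for img in batch_x])
            batch_y = targets[idx]
            masks = [sample_mask(n, config.mask_lower_ratio, rng) for _ in idx]
            states = np.stack([assign_states(y, m)
                               for y, m in zip(batch_y, masks)])
            probs = model.forward(batch_x, states, training=True, rng=rng)
            loss = masked_bce_loss(probs, batch_y, masks)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {epoch_steps}: {value}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            step_losses.append(value)
            epoch_sum += value
            epoch_steps += 1
        epoch_losses.append(epoch_sum / max(epoch_steps, 1))
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs} "
                f"mean masked BCE {epoch_losses[-1]:.4f}")
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            ckpt_path = out_dir / "checkpoint.npz"
            save_checkpoint(model, ckpt_path)
            trace = out_dir / "loss_trace.csv"
            with open(trace, "w") as fh:
                fh.write("step,loss\n")
                fh.writelines(f"{i},{v:.8f}\n" for i, v in enumerate(step_losses))
    result = {"step_losses": step_losses, "epoch_losses": epoch_losses,
              "checkpoint": str(ckpt_path) if ckpt_path else None}
    if out_dir is not None:
        import hashlib
        from dataclasses import asdict
        blob = json.dumps({"train": asdict(config),
                           "model": asdict(model.config)}, sort_keys=True)
        manifest = {"seed": config.seed, "epochs": config.epochs,
                    "optimizer": config.optimizer,
                    "learning_rate": config.learning_rate,
                    "batch_size": config.batch_size,
                    "mask_lower_ratio": config.mask_lower_ratio,
                    "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                    "final_loss": epoch_losses[-1] if epoch_losses else None}
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def predict(model: LMeRAN, images: np.ndarray,
            known_states=None, return_attention: bool = False):
    """Evaluation-mode probabilities for all labels.

    ``known_states`` optionally reveals a subset of labels: a mapping from
    label name (or index) to "positive"/"negative", or a full per-label
    state list.  Unlisted labels stay "unknown" — the default protocol is
    all-unknown, i.e. pure image-based prediction.
    """
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 2
    if single:
        images = images[None]
    batch = images.shape[0]
    if known_states is None:
        states = np.full((batch, model.n), STATES["unknown"], dtype=np.int64)
    elif isinstance(known_states, dict):
        states = np.full((batch, model.n), STATES["unknown"], dtype=np.int64)
        for key, val in known_states.items():
            idx = model.labels.index(key) if isinstance(key, str) else int(key)
            if val not in ("positive", "negative"):
                raise ValueError("known states must be 'positive' or 'negative'")
            states[:, idx] = STATES[val]
    else:
        states = encode_states(known_states, model.n)
        if states.shape[0] == 1 and batch > 1:
            states = np.repeat(states, batch, axis=0)
    out = model.forward(images, states, training=False,
                        return_attention=return_attention)
    if return_attention:
        probs, alphas = out
        probs = probs.data
        return (probs[0] if single else probs), alphas
    probs = out.data
    return probs[0] if single else probs
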