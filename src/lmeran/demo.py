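"""The desk-scale demonstration study: data, model, schedule, measurements.

This module pins the study conditions used by the shipped end-to-end
demonstrations (and by ``scripts/acceptance.py``): 500 training and 200
held-out synthetic images at 64 px (model input 56 px), six labels with
the default implication 0 -> 2 at 0.9, the tiny trainable backbone
(depth 32, 2 attention layers, 2 heads), and a two-phase Adam schedule
with crop/flip augmentation. Labels 1, 3, 4, 5 carry high-contrast
primitives and are image-discriminable; the implication pair (0 subtle,
2 occult) is only predictable through label dependencies.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig, TrainConfig
from .data import augment, preprocess
from .evaluation import auc
from .interpret import attention_heatmap, pseudo_segmentation_iou
from .model import LMeRAN, STATES
from .synthetic import CooccurrenceConfig, GeometryConfig, generate_samples
from .training import predict, train

__all__ = ["DISCRIMINABLE", "IMPLICATION_SOURCE", "IMPLICATION_TARGET",
           "demo_model_config", "fit_demo", "run_demo_seed",
           "heatmap_localisation"]

DISCRIMINABLE = (1, 3, 4, 5)
IMPLICATION_SOURCE, IMPLICATION_TARGET = 0, 2
N_TRAIN, N_TEST = 500, 200
RENDER_SIZE, INPUT_SIZE = 64, 56

# two-phase schedule: a warm phase fits the visible primitives, a low-rate
# phase consolidates the state-conditioning pathway
SCHEDULE = ((3e-3, 25), (7e-4, 45))


def demo_model_config(lam: float = 0.2,
                      transformer_block: bool = True) -> ModelConfig:
    return ModelConfig(backbone="tiny", input_size=INPUT_SIZE,
                       labels=[f"Lesion{i}" for i in range(6)],
                       heads=2, layers=2, lam=lam,
                       transformer_block=transformer_block)


def make_data(seed: int):
    """(train pairs, held-out images, held-out targets, held-out samples)."""
    cc = CooccurrenceConfig()
    geom = GeometryConfig(image_size=RENDER_SIZE)
    train_s = generate_samples(cc, count=N_TRAIN, seed=seed * 17 + 1,
                               geometry=geom)
    test_s = generate_samples(cc, count=N_TEST, seed=seed * 17 + 2,
                              geometry=geom)
    pairs = [(preprocess(s.image, size=INPUT_SIZE).astype(np.float32), s.y)
             for s in train_s]
    x_test = np.stack([preprocess(s.image, size=INPUT_SIZE)
                       for s in test_s]).astype(np.float32)
    y_test = np.stack([s.y for s in test_s])
    return pairs, x_test, y_test, test_s


def fit_demo(model: LMeRAN, pairs, seed: int) -> LMeRAN:
    model.astype(np.float32)
    for phase, (lr, epochs) in enumerate(SCHEDULE):
        train(model, pairs,
              TrainConfig(learning_rate=lr, batch_size=32, epochs=epochs,
                          seed=seed + 1000 * phase),
              augment=augment)
    return model


def run_demo_seed(seed: int, lam: float = 0.2) -> dict:
    """Train one model under the study conditions and measure everything.

    Returns per-label held-out AUCs, the conditional-inference lift on the
    occult implication target, its revealed-vs-unknown AUC pair, the fitted
    model, and the held-out data for further probing.
    """
    pairs, x_test, y_test, test_s = make_data(seed)
    model = fit_demo(LMeRAN(demo_model_config(lam=lam), rng=seed), pairs, seed)

    scores = predict(model, x_test)
    per_label = [auc(scores[:, j], y_test[:, j]) for j in range(model.n)]

    cond = predict(model, x_test,
                   known_states={IMPLICATION_SOURCE: "positive"})
    lift = float(cond[:, IMPLICATION_TARGET].mean()
                 - scores[:, IMPLICATION_TARGET].mean())

    # replay regime: target unknown, every other label's true state revealed
    revealed = np.where(y_test > 0, STATES["positive"], STATES["negative"])
    revealed[:, IMPLICATION_TARGET] = STATES["unknown"]
    rev_scores = model.forward(x_test, revealed).data[:, IMPLICATION_TARGET]
    return {
        "seed": seed,
        "model": model,
        "per_label_auc": per_label,
        "lift": lift,
        "target_auc_unknown": auc(scores[:, IMPLICATION_TARGET],
                                  y_test[:, IMPLICATION_TARGET]),
        "target_auc_revealed": auc(rev_scores, y_test[:, IMPLICATION_TARGET]),
        "scores": scores,
        "x_test": x_test,
        "y_test": y_test,
        "test_samples": test_s,
    }


def heatmap_localisation(model: LMeRAN, test_samples, x_test,
                         labels=DISCRIMINABLE, max_images: int = 100):
    """Hit rate of heatmap argmax inside the planted box, and mean IoU."""
    scale = INPUT_SIZE / RENDER_SIZE
    hits, ious, n_eval = 0, [], 0
    for sample, image in zip(test_samples[:max_images], x_test[:max_images]):
        for j in labels:
            if not sample.y[j]:
                continue
            hm = attention_heatmap(model, image, j)
            x, y0, w, h = (np.asarray(sample.boxes[j], dtype=float) * scale)
            r, c = np.unravel_index(int(np.argmax(hm)), hm.shape)
            hits += (y0 <= r < y0 + h) and (x <= c < x + w)
            ious.append(float(pseudo_segmentation_iou(hm, (x, y0, w, h))))
            n_eval += 1
    return hits / max(n_eval, 1), float(np.mean(ious)) if ious else 0.0, n_eval
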