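"""Synthetic multi-label lesion images with planted co-occurrence structure.

The generator emulates the structure of a chest-radiograph screening task
at desk scale: mostly-background grayscale images in which each positive
label contributes one small localized primitive (disc / square / annulus /
bar, label-specific intensity and home position), plus a smooth
low-frequency background field and Gaussian pixel noise.  Label vectors
are drawn from an acyclic implication graph — base labels are independent
Bernoulli draws, then each implication (a -> b, q) switches b on with
probability q whenever a is on — so conditional dependence between labels
is planted and measurable.

Every operation is deterministic given its seed; the background field and
each label's primitive consume independent random streams, so toggling one
label changes pixels only inside that label's box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import BoxRecord, LabelRecord, write_bbox_csv, write_label_csv

__all__ = ["CooccurrenceConfig", "GeometryConfig", "SyntheticSample",
           "sample_labels", "render_image", "generate_samples",
           "generate_dataset", "default_label_names"]

_SHAPES = ("disc", "square", "annulus", "bar")


@dataclass(frozen=True)
class CooccurrenceConfig:
    """Label-vector distribution: marginals plus an implication DAG."""

    n: int = 6
    base_probs: tuple = None
    implications: tuple = ((0, 2, 0.9),)

    # default marginals: the implication source (0) is common, the target (2)
    # rare at baseline so the planted dependence dominates its occurrence
    _default_probs = (0.40, 0.35, 0.25, 0.35, 0.35, 0.35)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one label")
        probs = self.base_probs
        if probs is None:
            probs = (self._default_probs * (self.n // 6 + 1))[:self.n] \
                if self.n >= 6 else (0.35,) * self.n
        probs = tuple(float(p) for p in np.broadcast_to(probs, self.n))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("base probabilities must lie in [0, 1]")
        object.__setattr__(self, "base_probs", probs)
        imps = self.implications
        if imps == type(self).implications and self.n < 3:
            imps = ()  # the default edge needs at least 3 labels
        imps = tuple((int(a), int(b), float(q)) for a, b, q in imps)
        for a, b, q in imps:
            if not (0 <= a < self.n and 0 <= b < self.n) or a == b:
                raise ValueError(f"bad implication ({a}, {b}, {q})")
            if not 0.0 <= q <= 1.0:
                raise ValueError("implication probability must lie in [0, 1]")
        object.__setattr__(self, "implications", imps)
        self._topo_order()  # raises on cycles

    def _topo_order(self) -> list:
        children: dict = {i: [] for i in range(self.n)}
        indeg = {i: 0 for i in range(self.n)}
        for a, b, _ in self.implications:
            children[a].append(b)
            indeg[b] += 1
        queue = [i for i in range(self.n) if indeg[i] == 0]
        order = []
        while queue:
            node = queue.pop()
            order.append(node)
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != self.n:
            raise ValueError("implication graph contains a cycle")
        return order


@dataclass(frozen=True)
class GeometryConfig:
    """Where and how each label's primitive is drawn.

    Primitives sit at label-specific home positions on a ring around the
    image centre, jittered per image; shapes and intensity contrasts cycle
    through label-specific values.  Sizes scale with the image so the same
    geometry works at 112 (test default) and 448.
    """

    image_size: int = 112
    primitive_scale: float = 0.09   # primitive radius as fraction of image side
    jitter: float = 0.04            # positional jitter fraction
    ring_radius: float = 0.30       # home-position ring radius fraction
    background_level: float = 0.30
    background_amplitude: float = 0.10
    # shape cycles with period 4, so labels sharing a shape are given
    # well-separated intensity contrasts: identity must be readable from
    # content alone (the attention stack carries no positional encoding).
    # The default implication pair is deliberately hard to see: label 0 is
    # subtle (contrast at the background variation) and label 2 is occult
    # (zero contrast — a finding present in the record but invisible in
    # the pixels, as report-derived annotations often are), so inferring
    # them requires the label co-occurrence structure and revealed label
    # states, not just pixels; labels 1, 3, 4, 5 are the high-contrast,
    # image-discriminable ones.
    contrasts: tuple = (0.08, 0.45, 0.0, 0.55, 0.35, 0.70)

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image size must be at least 64")

    def home_position(self, label: int, n: int) -> tuple:
        angle = 2.0 * np.pi * label / max(n, 1)
        c = self.image_size / 2.0
        r = self.ring_radius * self.image_size
        return c + r * np.cos(angle), c + r * np.sin(angle)

    def contrast(self, label: int) -> float:
        return self.contrasts[label % len(self.contrasts)]

    @staticmethod
    def shape(label: int) -> str:
        return _SHAPES[label % len(_SHAPES)]


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray
    y: np.ndarray
    boxes: dict   # label index -> (x, y, w, h), tight around the primitive


def sample_labels(cfg: CooccurrenceConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Ancestral draw: independent base Bernoullis, then implications."""
    y = (rng.random(cfg.n) < np.asarray(cfg.base_probs)).astype(np.int64)
    pos = {label: i for i, label in enumerate(cfg._topo_order())}
    for a, b, q in sorted(cfg.implications, key=lambda edge: pos[edge[0]]):
        if y[a] and rng.random() < q:
            y[b] = 1
    return y


def _primitive_mask(shape: str, cx: float, cy: float, radius: float,
                    size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    if shape == "disc":
        return dx**2 + dy**2 <= radius**2
    if shape == "square":
        return (np.abs(dx) <= radius) & (np.abs(dy) <= radius)
    if shape == "annulus":
        rr = dx**2 + dy**2
        return (rr <= radius**2) & (rr >= (0.5 * radius) ** 2)
    if shape == "bar":
        return (np.abs(dx) <= radius) & (np.abs(dy) <= 0.5 * radius)
    raise ValueError(f"unknown primitive shape {shape!r}")


def _background(geometry: GeometryConfig, noise_sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    size = geometry.image_size
    yy, xx = np.mgrid[0:size, 0:size] / size
    field = np.full((size, size), geometry.background_level)
    for _ in range(3):  # a few low-frequency cosine components
        ux, uy = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = geometry.background_amplitude / 3.0
        field += amp * np.cos(2 * np.pi * (ux * xx + uy * yy) + phase)
    if noise_sigma > 0:
        field += rng.normal(0.0, noise_sigma, size=(size, size))
    return field


def render_image(y, geometry: GeometryConfig | None = None,
                 noise_sigma: float = 0.03, seed: int = 0) -> SyntheticSample:
    """Render one sample; deterministic given (y, seed).

    The background and each label's jitter use independent streams derived
    from ``seed``, so two renders with the same seed but different label
    vectors agree pixel-for-pixel outside the toggled labels' boxes.
    """
    geometry = geometry or GeometryConfig()
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    size = geometry.image_size
    seed_key = list(np.atleast_1d(np.asarray(seed, dtype=np.int64)))
    bg_rng = np.random.default_rng(np.random.SeedSequence([*seed_key, 0]))
    image = _background(geometry, noise_sigma, bg_rng)
    boxes: dict = {}
    radius = geometry.primitive_scale * size
    jitter = geometry.jitter * size
    for label in np.flatnonzero(y):
        lab_rng = np.random.default_rng(
            np.random.SeedSequence([*seed_key, int(label) + 1]))
        cx, cy = geometry.home_position(int(label), n)
        cx += lab_rng.uniform(-jitter, jitter)
        cy += lab_rng.uniform(-jitter, jitter)
        margin = radius + 1
        cx = float(np.clip(cx, margin, size - 1 - margin))
        cy = float(np.clip(cy, margin, size - 1 - margin))
        mask = _primitive_mask(geometry.shape(int(label)), cx, cy, radius, size)
        image = np.where(mask, image + geometry.contrast(int(label)), image)
        rows, cols = np.nonzero(mask)
        x0, y0 = int(cols.min()), int(rows.min())
        boxes[int(label)] = (x0, y0, int(cols.max()) - x0 + 1,
                             int(rows.max()) - y0 + 1)
    return SyntheticSample(np.clip(image, 0.0, 1.0), y, boxes)


def default_label_names(n: int) -> list:
    return [f"Lesion{i}" for i in range(n)]


def generate_samples(cfg: CooccurrenceConfig | None = None, count: int = 100,
                     seed: int = 0, geometry: GeometryConfig | None = None,
                     noise_sigma: float = 0.03) -> list:
    """In-memory dataset: ``count`` SyntheticSamples, deterministic in seed."""
    cfg = cfg or CooccurrenceConfig()
    label_rng = np.random.default_rng(np.random.SeedSequence([seed, 999_999]))
    return [
        render_image(sample_labels(cfg, label_rng), geometry=geometry,
                     noise_sigma=noise_sigma, seed=(seed, i))
        for i in range(count)
    ]


def generate_dataset(cfg: CooccurrenceConfig | None = None, count: int = 100,
                     seed: int = 0, out_dir=".",
                     geometry: GeometryConfig | None = None,
                     noise_sigma: float = 0.03,
                     label_names=None) -> dict:
    """Write images + label CSV + bbox CSV + manifest in the standard dialects."""
    cfg = cfg or CooccurrenceConfig()
    geometry = geometry or GeometryConfig()
    names = label_names or default_label_names(cfg.n)
    if len(names) != cfg.n:
        raise ValueError("label name count must match cfg.n")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    samples = generate_samples(cfg, count, seed, geometry, noise_sigma)
    records, boxes = [], []
    for i, sample in enumerate(samples):
        image_id = f"synth_{i:05d}.png"
        arr = np.round(sample.image * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / "images" / image_id)
        records.append(LabelRecord(
            image_id, frozenset(names[j] for j in np.flatnonzero(sample.y))))
        for j, (x, y0, w, h) in sorted(sample.boxes.items()):
            boxes.append(BoxRecord(image_id, names[j], x, y0, w, h))
    write_label_csv(records, out / "labels.csv")
    write_bbox_csv(boxes, out / "bbox.csv")
    manifest = {
        "seed": seed, "count": count, "noise_sigma": noise_sigma,
        "labels": list(names),
        "cooccurrence": {"n": cfg.n, "base_probs": list(cfg.base_probs),
                         "implications": [list(i) for i in cfg.implications]},
        "geometry": {"image_size": geometry.image_size,
                     "primitive_scale": geometry.primitive_scale,
                     "jitter": geometry.jitter,
                     "ring_radius": geometry.ring_radius},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
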