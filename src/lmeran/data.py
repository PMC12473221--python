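"""Readers/writers for images, label CSVs and box CSVs, plus preprocessing.

The label CSV dialect follows the ChestX-ray14 convention: an ``Image
Index`` column with the image filename and a ``Finding Labels`` column with
pipe-separated finding names, the literal ``No Finding`` standing for an
all-negative record.  Bounding boxes are ``Image Index, Finding Label,
x, y, w, h`` in original-image pixel coordinates (0-based, x right,
y down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CHESTXRAY14_LABELS", "NO_FINDING", "LabelRecord", "BoxRecord",
    "read_label_csv", "write_label_csv", "to_target", "from_target",
    "label_statistics", "load_image", "preprocess", "augment",
    "SplitSpec", "load_split", "read_bbox_csv", "write_bbox_csv", "scale_box",
]

NO_FINDING = "No Finding"

CHESTXRAY14_LABELS = [
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural Thickening", "Hernia",
]


@dataclass(frozen=True)
class LabelRecord:
    image_id: str
    findings: frozenset

    def __post_init__(self):
        if NO_FINDING in self.findings and len(self.findings) > 1:
            raise ValueError(f"{self.image_id}: 'No Finding' cannot co-occur "
                             "with a finding")


@dataclass(frozen=True)
class BoxRecord:
    image_id: str
    finding: str
    x: float
    y: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"{self.image_id}: box must have positive extent")


def read_label_csv(path, vocabulary=None, strict: bool = True) -> list:
    """Parse a label CSV; unknown finding names raise (strict) or warn."""
    df = pd.read_csv(path, skipinitialspace=True)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        id_col = cols["image index"]
        lab_col = cols["finding labels"]
    except KeyError as exc:
        raise ValueError(f"missing column in label CSV: {exc}") from exc
    records = []
    for _, row in df.iterrows():
        raw = str(row[lab_col]).strip()
        names = {s.strip() for s in raw.split("|") if s.strip()}
        if names == {NO_FINDING}:
            names = set()
        elif NO_FINDING in names:
            raise ValueError(f"{row[id_col]}: 'No Finding' mixed with findings")
        if vocabulary is not None:
            unknown = names - set(vocabulary)
            if unknown:
                if strict:
                    raise ValueError(f"unknown finding name(s) {sorted(unknown)}")
                warnings.warn(f"dropping unknown finding name(s) {sorted(unknown)}",
                              stacklevel=2)
                names -= unknown
        records.append(LabelRecord(str(row[id_col]).strip(), frozenset(names)))
    return records


def write_label_csv(records, path) -> None:
    rows = [{"Image Index": r.image_id,
             "Finding Labels": "|".join(sorted(r.findings)) or NO_FINDING}
            for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def to_target(record: LabelRecord, vocabulary) -> np.ndarray:
    """Binary target vector in vocabulary order; empty findings -> all zero."""
    return np.array([1 if name in record.findings else 0 for name in vocabulary],
                    dtype=np.int64)


def from_target(image_id: str, y, vocabulary) -> LabelRecord:
    findings = frozenset(name for name, v in zip(vocabulary, y) if v)
    return LabelRecord(image_id, findings)


def label_statistics(records=None, vocabulary=None, *, counts=None) -> pd.DataFrame:
    """Per-label quantity and frequency, 'No Finding' counted as an instance.

    Either ``records`` (with an optional vocabulary fixing row order) or a
    precomputed ``counts`` mapping label -> quantity may be given.  The
    frequency column is quantity / total label instances * 100, so the
    frequencies sum to 100% up to rounding.
    """
    if counts is None:
        if not records:
            raise ValueError("no records given")
        counts = {}
        for rec in records:
            names = rec.findings or {NO_FINDING}
            for name in names:
                counts[name] = counts.get(name, 0) + 1
        if vocabulary is not None:
            counts = {k: counts.get(k, 0) for k in [NO_FINDING, *vocabulary]}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no label instances")
    df = pd.DataFrame({"Labels": list(counts), "Quantity": list(counts.values())})
    df["Frequency"] = df["Quantity"] / total * 100.0
    return df.sort_values("Quantity", ascending=False, ignore_index=True)


def load_image(path) -> np.ndarray:
    """Decode an image file to a 2-D float array in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("F"), dtype=np.float64)
    return arr / 255.0


def preprocess(image: np.ndarray, size: int = 448) -> np.ndarray:
    """Bilinear resize to size x size and scale intensities to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixel intensities")
    if image.max() > 1.0:
        image = image / 255.0
    if image.shape != (size, size):
        image = np.asarray(
            Image.fromarray(image.astype(np.float32), mode="F")
            .resize((size, size), Image.BILINEAR), dtype=np.float64)
    return np.clip(image, 0.0, 1.0)


def augment(image: np.ndarray, rng: np.random.Generator,
            scale_range: tuple = (0.8, 1.0), flip_prob: float = 0.5) -> np.ndarray:
    """Random area crop (resized back) and horizontal flip; train-time only."""
    image = np.asarray(image)
    dtype = image.dtype if image.dtype == np.float32 else np.float64
    image = image.astype(np.float64, copy=False)
    h, w = image.shape
    area = rng.uniform(*scale_range)
    side_h = max(1, int(round(h * np.sqrt(area))))
    side_w = max(1, int(round(w * np.sqrt(area))))
    top = int(rng.integers(0, h - side_h + 1))
    left = int(rng.integers(0, w - side_w + 1))
    crop = image[top:top + side_h, left:left + side_w]
    out = np.asarray(
        Image.fromarray(crop.astype(np.float32), mode="F").resize(
            (w, h), Image.BILINEAR), dtype=np.float64)
    if rng.random() < flip_prob:
        out = out[:, ::-1]
    return np.ascontiguousarray(out, dtype=dtype)


@dataclass(frozen=True)
class SplitSpec:
    train: tuple
    validation: tuple
    test: tuple
    patient_disjoint: bool = False

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        if sum(len(p) for p in parts) != len(set().union(*parts)):
            raise ValueError("split lists overlap")


def _patient_id(image_id: str) -> str:
    return image_id.split("_")[0]


def load_split(image_ids=None, ratio=(0.7, 0.1, 0.2), rng=None,
               patient_disjoint: bool = False, lists=None) -> SplitSpec:
    """Build a train/validation/test split.

    Either ``lists`` (three explicit id lists, kept verbatim) or
    ``image_ids`` plus a ratio and seeded generator.  In
    ``patient_disjoint`` mode whole patients (id prefix before the first
    underscore) are assigned to one split.
    """
    if lists is not None:
        tr, va, te = lists
        return SplitSpec(tuple(tr), tuple(va), tuple(te),
                         patient_disjoint=patient_disjoint)
    if image_ids is None:
        raise ValueError("need image_ids or explicit lists")
    if not np.isclose(sum(ratio), 1.0):
        raise ValueError("split ratio must sum to 1")
    rng = np.random.default_rng() if rng is None else rng
    ids = list(image_ids)
    if patient_disjoint:
        patients = sorted({_patient_id(i) for i in ids})
        order = list(rng.permutation(patients))
        n_tr = int(round(ratio[0] * len(order)))
        n_va = int(round(ratio[1] * len(order)))
        groups = (set(order[:n_tr]), set(order[n_tr:n_tr + n_va]),
                  set(order[n_tr + n_va:]))
        parts = tuple(tuple(i for i in ids if _patient_id(i) in grp)
                      for grp in groups)
        return SplitSpec(*parts, patient_disjoint=True)
    order = list(rng.permutation(ids))
    n_tr = int(round(ratio[0] * len(order)))
    n_va = int(round(ratio[1] * len(order)))
    return SplitSpec(tuple(order[:n_tr]), tuple(order[n_tr:n_tr + n_va]),
                     tuple(order[n_tr + n_va:]))


def scale_box(box: BoxRecord, original_size: int, target_size: int) -> BoxRecord:
    """Rescale box coordinates from original to preprocessed image size."""
    f = target_size / original_size
    return BoxRecord(box.image_id, box.finding,
                     box.x * f, box.y * f, box.w * f, box.h * f)


def read_bbox_csv(path, original_size: int | None = None,
                  target_size: int | None = None) -> list:
    """Parse a bbox CSV; optionally rescale from original to target size."""
    df = pd.read_csv(path, skipinitialspace=True)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        id_col, lab_col = cols["image index"], cols["finding label"]
        xc, yc, wc, hc = cols["x"], cols["y"], cols["w"], cols["h"]
    except KeyError as exc:
        raise ValueError(f"missing column in bbox CSV: {exc}") from exc
    boxes = []
    for _, row in df.iterrows():
        box = BoxRecord(str(row[id_col]).strip(), str(row[lab_col]).strip(),
                        float(row[xc]), float(row[yc]),
                        float(row[wc]), float(row[hc]))
        if original_size is not None and target_size is not None:
            box = scale_box(box, original_size, target_size)
            if box.x < 0 or box.y < 0 or box.x + box.w > target_size \
                    or box.y + box.h > target_size:
                raise ValueError(f"{box.image_id}: box out of bounds after scaling")
        boxes.append(box)
    return boxes


def write_bbox_csv(boxes, path) -> None:
    rows = [{"Image Index": b.image_id, "Finding Label": b.finding,
             "x": b.x, "y": b.y, "w": b.w, "h": b.h} for b in boxes]
    pd.DataFrame(rows).to_csv(path, index=False)
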