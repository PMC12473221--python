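"""Attention heatmaps and pseudo-segmentation IoU against lesion boxes.

A heatmap for label i is read off the attention stack: the query row of
label token i, restricted to the image-patch keys, reduced over heads,
reshaped to the h x w patch grid, bilinearly upsampled to image size and
min-max normalised to [0, 1].  Thresholding the normalised intensities at
a cutoff (strictly greater than 0.4 by default) yields a binary
pseudo-segmentation whose overlap with a ground-truth box is scored by
intersection-over-union.
"""

from __future__ import annotations

import warnings

import numpy as np
from PIL import Image

from .model import LMeRAN, STATES

__all__ = ["attention_heatmap", "upsample_bilinear", "normalize_heatmap",
           "pseudo_segmentation_iou", "IoUResult", "box_to_mask"]


def upsample_bilinear(grid: np.ndarray, size: tuple) -> np.ndarray:
    """Bilinearly resize a 2-D float grid to (height, width)."""
    img = Image.fromarray(np.asarray(grid, dtype=np.float32), mode="F")
    return np.asarray(img.resize((size[1], size[0]), Image.BILINEAR),
                      dtype=np.float64)


def normalize_heatmap(hm: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant map becomes all-zeros."""
    lo, hi = float(hm.min()), float(hm.max())
    if hi - lo < 1e-12:
        warnings.warn("constant heatmap: normalising to all-zeros", stacklevel=2)
        return np.zeros_like(hm, dtype=np.float64)
    return (hm - lo) / (hi - lo)


def attention_heatmap(model: LMeRAN, image: np.ndarray, label_index: int,
                      layer: int = -1, head_reduce: str = "mean",
                      states=None) -> np.ndarray:
    """Lesion-localisation heatmap for one label on one image.

    ``layer`` selects the attention layer (default last); ``head_reduce``
    is "mean", "max", or a head index.  Returns a float array the size of
    the input image with values in [0, 1].
    """
    if not 0 <= label_index < model.n:
        raise ValueError(f"label index {label_index} out of range")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D grayscale image")
    if states is None:
        states = np.full(model.n, STATES["unknown"], dtype=np.int64)
    _, alphas = model.forward(image[None], states, training=False,
                              return_attention=True)
    alpha = alphas[layer][0]                      # (p, M, M)
    hw = model.h * model.w
    row = alpha[:, hw + label_index, :hw]         # label query over patch keys
    if head_reduce == "mean":
        row = row.mean(axis=0)
    elif head_reduce == "max":
        row = row.max(axis=0)
    else:
        row = row[int(head_reduce)]
    grid = row.reshape(model.h, model.w)
    hm = upsample_bilinear(grid, image.shape)
    return normalize_heatmap(hm)


def box_to_mask(box, shape: tuple) -> np.ndarray:
    """Rasterise an (x, y, w, h) box (0-based, x right / y down) to a mask."""
    x, y, w, h = box
    if w <= 0 or h <= 0:
        raise ValueError("box must have positive extent")
    height, width = shape
    x0, y0 = int(round(x)), int(round(y))
    x1, y1 = int(round(x + w)), int(round(y + h))
    if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
        raise ValueError("box exceeds image bounds")
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = True
    return mask


class IoUResult(float):
    """IoU score carrying the two binary masks it was computed from."""

    def __new__(cls, iou, predicted_mask, truth_mask, threshold):
        obj = super().__new__(cls, iou)
        obj.iou = float(iou)
        obj.predicted_mask = predicted_mask
        obj.truth_mask = truth_mask
        obj.threshold = threshold
        return obj


def pseudo_segmentation_iou(heatmap: np.ndarray, box,
                            threshold: float = 0.4) -> IoUResult:
    """IoU between {pixels with intensity > threshold} and a truth box."""
    heatmap = np.asarray(heatmap, dtype=np.float64)
    predicted = heatmap > threshold
    truth = box if isinstance(box, np.ndarray) and box.dtype == bool \
        else box_to_mask(box, heatmap.shape)
    union = np.logical_or(predicted, truth).sum()
    if union == 0:
        warnings.warn("empty union: IoU defined as 0", stacklevel=2)
        return IoUResult(0.0, predicted, truth, threshold)
    inter = np.logical_and(predicted, truth).sum()
    return IoUResult(inter / union, predicted, truth, threshold)
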