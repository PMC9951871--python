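"""Segmentation, inpainting and clinically-relevant tissue metrics.

Dice overlap scores model accuracy; the inpainting metric is the Euclidean
(L2) norm of the difference image in normalized space, averaged over
channels for multi-channel CT.  Clinical metrics quantify what a
radiologist would derive from the segmentation: tissue volume and mean T2
relaxation time for MRI, cross-sectional area and mean HU for CT.  Percent
errors compare metrics computed from predicted segmentations against the
same metrics from ground-truth segmentations; HU means are always taken on
the raw (un-windowed, un-normalized) HU image so the values remain
physically meaningful.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "dice_score",
    "inpainting_l2",
    "tissue_volume",
    "mean_t2",
    "cross_sectional_area",
    "mean_hu",
    "percent_error",
    "per_image_comparison",
]


def _check_same_shape(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_score(pred_labels: np.ndarray, true_labels: np.ndarray, class_id: int) -> float:
    """Hard Dice coefficient ``2|P & G| / (|P| + |G|)`` for one class.

    Defined as 1.0 when both masks are empty (perfect agreement on absence).
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    _check_same_shape(pred_labels, true_labels)
    p = pred_labels == class_id
    g = true_labels == class_id
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def inpainting_l2(reconstruction: np.ndarray, original: np.ndarray) -> float:
    """Euclidean norm of the difference image in normalized space.

    Single channel: plain flat-vector L2 norm.  Multi-channel: the norm is
    computed per channel and averaged across channels.
    """
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    _check_same_shape(reconstruction, original)
    diff = reconstruction - original
    if diff.ndim == 2:
        return float(np.linalg.norm(diff.ravel()))
    if diff.ndim == 3:
        norms = [np.linalg.norm(diff[c].ravel()) for c in range(diff.shape[0])]
        return float(np.mean(norms))
    raise ValueError(f"expected (H, W) or (C, H, W) images, got shape {diff.shape}")


def _class_pixels(label_map, class_id):
    return np.asarray(label_map) == class_id


def tissue_volume(
    label_maps: np.ndarray | Sequence[np.ndarray],
    pixel_spacing: float,
    slice_thickness: float,
    class_id: int,
) -> float:
    """Tissue volume in mm^3: pixel count x spacing^2 x slice thickness,
    summed over slices.  Accepts one 2D map or a stack/sequence of them."""
    if pixel_spacing <= 0 or slice_thickness <= 0:
        raise ValueError("pixel_spacing and slice_thickness must be > 0")
    maps = np.asarray(label_maps)
    if maps.ndim == 2:
        maps = maps[None]
    count = int((maps == class_id).sum())
    return count * pixel_spacing**2 * slice_thickness


def mean_t2(t2_map: np.ndarray, label_map: np.ndarray, class_id: int) -> float:
    """Mean T2 relaxation time (ms) over the class mask; NaN for an empty
    mask (undefined, never silently 0)."""
    t2_map = np.asarray(t2_map)
    _check_same_shape(t2_map, np.asarray(label_map))
    mask = _class_pixels(label_map, class_id)
    if not mask.any():
        return math.nan
    return float(t2_map[mask].mean())


def cross_sectional_area(label_map: np.ndarray, pixel_spacing: float, class_id: int) -> float:
    """Cross-sectional area in mm^2: pixel count x spacing^2."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    return int(_class_pixels(label_map, class_id).sum()) * pixel_spacing**2


def mean_hu(hu_image: np.ndarray, label_map: np.ndarray, class_id: int) -> float:
    """Mean HU over the class mask, computed on the raw HU image; NaN for an
    empty mask."""
    hu_image = np.asarray(hu_image)
    _check_same_shape(hu_image, np.asarray(label_map))
    mask = _class_pixels(label_map, class_id)
    if not mask.any():
        return math.nan
    return float(hu_image[mask].mean())


def percent_error(predicted: float, ground_truth: float) -> float:
    """Unsigned percent error ``100 * |pred - gt| / |gt|``; NaN when the
    ground-truth value is 0 (undefined)."""
    if ground_truth == 0 or not math.isfinite(ground_truth):
        return math.nan
    return 100.0 * abs(predicted - ground_truth) / abs(ground_truth)


def per_image_comparison(
    supervised_errors: pd.DataFrame,
    ssl_errors: pd.DataFrame,
    exclude_classes: Sequence[int] = (),
) -> pd.DataFrame:
    """Pair supervised and SSL percent errors per test image.

    Inputs are long tables with columns ``image_id, class_id, regime,
    percent_error`` covering the same (image, class, regime) index set.  For
    each image the percent error is averaged over all classes and
    label-limited regimes (optionally excluding named classes, e.g. a tissue
    whose tiny area makes its percent error explode); the output has one row
    per image with columns ``supervised, ssl, difference`` (supervised minus
    SSL, positive when SSL is better).
    """
    required = {"image_id", "class_id", "regime", "percent_error"}
    for name, df in (("supervised", supervised_errors), ("ssl", ssl_errors)):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{name} table is missing columns {sorted(missing)}")

    def collapse(df):
        df = df[~df["class_id"].isin(list(exclude_classes))]
        return df.groupby("image_id")["percent_error"].mean()

    sup = collapse(supervised_errors)
    ssl = collapse(ssl_errors)
    if not sup.index.equals(ssl.index):
        raise ValueError("supervised and ssl tables cover different image sets")
    out = pd.DataFrame({"supervised": sup, "ssl": ssl})
    out["difference"] = out["supervised"] - out["ssl"]
    return out
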