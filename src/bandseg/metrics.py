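"""Segmentation quality metrics: distance- and overlap-based.

Contour distances (MAD, its std, Max-AD) are computed over corresponding
points; masks are compared through the TP/FP/FN/TN confusion counts:

    Dice = 2TP / (2TP + FP + FN)
    IoU  = TP / (TP + FP + FN)
    FPR  = FP / (FP + TN)

Degenerate conventions: both masks empty gives Dice = IoU = 1 (perfect
agreement on nothing); FPR with no true negatives is 0.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from ._errors import ValidationError
from .contour import as_contour, ensure_ccw, resample_contour

__all__ = [
    "mad",
    "overlap_metrics",
    "contour_to_mask",
]


def mad(pred, truth, pixel_spacing: float = 1.0, n_points: int | None = None):
    """Mean / std / max absolute deviation between corresponding points.

    Correspondence rule: both contours are oriented CCW, resampled to the
    same number of points at uniform arc length, and the truth sequence is
    rolled so its start is the point nearest the prediction's start.
    Distances are multiplied by ``pixel_spacing`` (mm/px), so results are in
    mm when a spacing is given and px otherwise.

    Returns (mean, std, max).
    """
    p = ensure_ccw(as_contour(pred))
    t = ensure_ccw(as_contour(truth))
    n = n_points or max(p.shape[0], t.shape[0])
    p = resample_contour(p, n)
    t = resample_contour(t, n)
    if p.shape[0] != t.shape[0]:
        raise ValidationError("point counts differ after resampling")
    start = int(np.argmin(np.linalg.norm(t - p[0], axis=1)))
    t = np.roll(t, -start, axis=0)
    d = np.linalg.norm(p - t, axis=1) * pixel_spacing
    return float(d.mean()), float(d.std()), float(d.max())


def _as_binary(mask, name):
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValidationError(f"{name} mask is not binary")
        m = m.astype(bool)
    return m


def overlap_metrics(predicted, truth) -> dict:
    """Dice, IoU and FPR from the confusion counts of two binary masks."""
    p = _as_binary(predicted, "predicted")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    iou = 1.0 if (tp + fp + fn) == 0 else tp / (tp + fp + fn)
    fpr = 0.0 if (fp + tn) == 0 else fp / (fp + tn)
    return {"dice": dice, "iou": iou, "fpr": fpr}


def contour_to_mask(c, shape, check_simple: bool = True) -> np.ndarray:
    """Rasterize a closed contour: pixels with centers inside the polygon.

    A zero-area contour yields an empty mask; a self-intersecting contour is
    an error (set ``check_simple=False`` to skip the validity check).
    """
    p = as_contour(c)
    poly = Polygon(p)
    if poly.area == 0.0:
        return np.zeros(shape, dtype=bool)
    if check_simple and not poly.is_valid:
        raise ValidationError("contour is self-intersecting")
    return polygon2mask(shape, p)
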