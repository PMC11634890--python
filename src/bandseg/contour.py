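"""Closed planar contours as ordered landmark sequences.

A contour is an ``(N, 2)`` float array of ``(row, col)`` pixel coordinates
describing a closed polygon (the closing edge from the last point back to the
first is implicit).  By package convention contours are stored
counter-clockwise in ``(row, col)`` coordinates, i.e. with positive signed
area under the shoelace formula with ``x = col`` and ``y = row``; inputs with
negative signed area are reversed on load.  A consistent orientation makes
"outward normal" unambiguous downstream.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from ._errors import ValidationError

__all__ = [
    "as_contour",
    "signed_area",
    "ensure_ccw",
    "centroid",
    "perimeter",
    "resample_contour",
    "read_contour",
    "write_contour",
]


def as_contour(points, min_points: int = 3) -> np.ndarray:
    """Coerce ``points`` to a valid (N, 2) float contour array.

    Raises ``ValidationError`` if the shape is wrong, N < ``min_points``,
    coordinates are non-finite, or consecutive points coincide.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"contour must be (N, 2), got shape {arr.shape}")
    if arr.shape[0] < min_points:
        raise ValidationError(
            f"contour needs at least {min_points} points, got {arr.shape[0]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("contour contains non-finite coordinates")
    nxt = np.roll(arr, -1, axis=0)
    if np.any(np.all(arr == nxt, axis=1)):
        raise ValidationError("contour has coincident consecutive points")
    return arr


def signed_area(points) -> float:
    """Shoelace signed area with x = col, y = row; positive means CCW."""
    p = np.asarray(points, dtype=float)
    x = p[:, 1]
    y = p[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points) -> np.ndarray:
    """Return the contour with counter-clockwise orientation.

    The starting point is preserved; only the traversal direction may flip.
    """
    p = np.asarray(points, dtype=float)
    if signed_area(p) < 0:
        p = np.roll(p[::-1], 1, axis=0)
    return p


def centroid(points) -> np.ndarray:
    return np.mean(np.asarray(points, dtype=float), axis=0)


def perimeter(points) -> float:
    p = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))


def resample_contour(points, n: int) -> np.ndarray:
    """Resample a closed contour to ``n`` points at uniform arc length.

    The first output point is the input's first point and traversal keeps the
    stored orientation, so resampling fixes the sequence start used by the
    smoothing stage.  Total perimeter is preserved up to polygonal
    discretisation.
    """
    if n < 3:
        raise ValidationError(f"resample target must be >= 3, got {n}")
    p = as_contour(points)
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * total / n
    rows = np.interp(targets, cum, closed[:, 0])
    cols = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([rows, cols])


def read_contour(path, orient: bool = True) -> np.ndarray:
    """Read a contour from CSV (header ``row,col``) or JSON (list of pairs)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        pts = np.asarray(data, dtype=float)
    else:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
        if not rows:
            raise ValidationError(f"empty contour file: {path}")
        start = 1 if not _is_number_row(rows[0]) else 0
        pts = np.asarray([[float(r[0]), float(r[1])] for r in rows[start:]])
    c = as_contour(pts)
    return ensure_ccw(c) if orient else c


def write_contour(path, points) -> None:
    path = Path(path)
    p = as_contour(points)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(p.tolist()))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col"])
            writer.writerows(p.tolist())


def _is_number_row(row) -> bool:
    try:
        [float(v) for v in row[:2]]
        return True
    except (TypeError, ValueError):
        return False
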