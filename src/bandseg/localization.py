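"""Prior placement: affine transform localization and bilinear sampling.

The shape prior lives in a normalized model frame (zero centroid, unit
centroid size).  A transform-localization affine — translation ``(tx, ty)``
plus axis-aligned scales ``(t1, t2)`` — places it on the target image.  There
is deliberately no rotation parameter: moderate rotation is absorbed by the
shape model's modes, and any placement error up to the narrow-band half-length
is corrected by the downstream boundary search.

A learned localizer can be plugged in by supplying a ``TransformLocalization``
directly; ``moment_initializer`` provides a training-free default based on
image moments of the (inverted) hypoechoic target region.

Coordinates are (row, col), 0-based, with pixel centers at integers.
``tx``/``t1`` act on the horizontal (col) axis, ``ty``/``t2`` on the vertical
(row) axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._errors import ValidationError
from .contour import as_contour

__all__ = [
    "TransformLocalization",
    "apply_transform",
    "bilinear_sample",
    "moment_initializer",
]


@dataclass
class TransformLocalization:
    """Affine placement: col' = t1*col + tx, row' = t2*row + ty."""

    tx: float = 0.0
    ty: float = 0.0
    t1: float = 1.0
    t2: float = 1.0

    def __post_init__(self):
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValidationError(
                f"scale factors must be positive, got t1={self.t1}, t2={self.t2}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on column vectors [col, row, 1]."""
        return np.array(
            [
                [self.t1, 0.0, self.tx],
                [0.0, self.t2, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"tx": self.tx, "ty": self.ty, "t1": self.t1, "t2": self.t2})
        )

    @classmethod
    def from_json(cls, path) -> "TransformLocalization":
        d = json.loads(Path(path).read_text())
        return cls(tx=float(d["tx"]), ty=float(d["ty"]), t1=float(d["t1"]), t2=float(d["t2"]))


def apply_transform(tl: TransformLocalization, prior) -> np.ndarray:
    """Apply the homogeneous affine to each (row, col) point of the prior."""
    p = np.asarray(prior, dtype=float)
    if p.size == 0:
        raise ValidationError("empty prior contour")
    m = tl.matrix
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValidationError("singular transform localization matrix")
    homog = np.column_stack([p[:, 1], p[:, 0], np.ones(p.shape[0])])  # [col, row, 1]
    out = homog @ m.T
    out = out[:, :2] / out[:, 2:3]
    return np.column_stack([out[:, 1], out[:, 0]])  # back to (row, col)


def bilinear_sample(image, coords) -> np.ndarray:
    """Bilinearly interpolate ``image`` at fractional (row, col) positions.

    Implements the parameterized-sampling-grid kernel
    ``I'_i = Σ_n Σ_m I_nm · max(0, 1−|x_i−m|) · max(0, 1−|y_i−n|)``;
    coordinates outside the image are clamped to the nearest edge sample, so
    bands that straddle the border see the border value rather than zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("image must be a nonempty 2-D array")
    pts = np.asarray(coords, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.all(np.isfinite(pts)):
        raise ValidationError("non-finite sampling coordinate")
    h, w = img.shape
    r = np.clip(pts[:, 0], 0.0, h - 1.0)
    c = np.clip(pts[:, 1], 0.0, w - 1.0)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = r - r0
    fc = c - c0
    out = (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0, c1] * (1 - fr) * fc
        + img[r1, c0] * fr * (1 - fc)
        + img[r1, c1] * fr * fc
    )
    return out[0] if single else out


def moment_initializer(
    image,
    model,
    smooth_sigma: float = 6.0,
    trim_factor: float = 1.5,
    trim_iters: int = 3,
    scale_correction: float = 1.05,
) -> TransformLocalization:
    """Training-free affine initialization from image moments.

    The hypoechoic target appears dark, so the smoothed image is inverted and
    thresholded (Otsu); the translation is the intensity-weighted centroid of
    the squared above-threshold excess and the scales come from second
    central moments matched against the mean shape's extents.  Squaring the
    excess and iteratively re-estimating with weights trimmed to
    ``trim_factor`` times the current extent ellipse suppresses
    bright-after-inversion artifact regions (e.g. shadow wedges) attached to
    the target.  Deterministic for fixed input.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("image must be a nonempty 2-D array")
    if float(img.max()) == float(img.min()):
        raise ValidationError("no structure to localize: image has zero variance")

    inv = img.max() - ndimage.gaussian_filter(img, smooth_sigma)
    thr = threshold_otsu(inv)
    weights = np.clip(inv - thr, 0.0, None) ** 2
    if weights.sum() == 0.0:
        raise ValidationError("no structure to localize: empty foreground")

    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]

    def _moments(w):
        total = w.sum()
        rc = float((w * rows).sum() / total)
        cc = float((w * cols).sum() / total)
        sr = float(np.sqrt((w * (rows - rc) ** 2).sum() / total))
        sc = float(np.sqrt((w * (cols - cc) ** 2).sum() / total))
        return rc, cc, sr, sc

    rc, cc, sr, sc = _moments(weights)
    for _ in range(trim_iters):
        # semiaxis estimate is 2 sigma; keep weight within trim_factor of it
        ell = ((rows - rc) / max(sr, 1.0)) ** 2 + ((cols - cc) / max(sc, 1.0)) ** 2
        trimmed = np.where(ell <= (2.0 * trim_factor) ** 2, weights, 0.0)
        if trimmed.sum() == 0.0:
            break
        rc, cc, sr, sc = _moments(trimmed)

    # For a uniformly weighted ellipse, std along an axis = semiaxis / 2.
    # The squared-excess weighting tapers at the blurred boundary, which
    # shrinks the moment slightly; scale_correction compensates.
    semi_col = 2.0 * sc * scale_correction
    semi_row = 2.0 * sr * scale_correction

    mean = model.mean_contour
    half_col = (mean[:, 1].max() - mean[:, 1].min()) / 2.0
    half_row = (mean[:, 0].max() - mean[:, 0].min()) / 2.0
    if half_col <= 0 or half_row <= 0:
        raise ValidationError("degenerate mean shape: zero extent")

    t1 = semi_col / half_col
    t2 = semi_row / half_row
    mean_c = mean.mean(axis=0)
    # translation so that the (scaled) mean-shape centroid lands on the target
    tx = cc - t1 * mean_c[1]
    ty = rc - t2 * mean_c[0]
    return TransformLocalization(tx=tx, ty=ty, t1=t1, t2=t2)
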