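"""Narrow band of normal-vector profiles around a prior contour.

At each of the N prior-contour points a profile of 2L samples is taken along
the outward unit normal, at signed offsets −L…−1 (inside) and +1…+L (outside);
the contour point itself (offset 0) is excluded, so each profile has exactly
2L entries ordered inside→outside.  Stacking the N sample coordinate lists
gives the N×2L index matrix ``IM``; sampling the image there (bilinear, unit
step spacing) gives its grayscale counterpart ``GM = φ(IM)``.  The band is the
entire search space for the boundary: every downstream operator works on
signed band offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .contour import as_contour, centroid
from .localization import bilinear_sample

__all__ = [
    "NarrowBand",
    "compute_normals",
    "build_narrowband",
    "signed_offsets",
    "offset_to_column",
    "column_to_offset",
    "band_to_contour",
    "offsets_to_contour",
]


def compute_normals(c) -> np.ndarray:
    """Unit outward normals from cyclic central-difference tangents.

    The normal at point k is perpendicular to ``p[k+1] − p[k−1]`` and oriented
    away from the contour centroid (positive dot product with the
    centroid-to-point vector).
    """
    p = as_contour(c)
    tangent = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    if np.any(norms == 0):
        raise ValidationError("coincident neighbouring points: zero tangent")
    tangent = tangent / norms[:, None]
    # rotate tangent (dr, dc) by 90 degrees -> (dc, -dr)
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    outward = p - centroid(p)
    flip = np.sum(normal * outward, axis=1) < 0
    normal[flip] *= -1.0
    return normal


def signed_offsets(L: int) -> np.ndarray:
    """Band offsets in column order: −L…−1, +1…+L."""
    return np.concatenate([np.arange(-L, 0), np.arange(1, L + 1)])


def offset_to_column(offset, L: int):
    """Signed nonzero offset -> band column index (0…2L−1)."""
    off = np.asarray(offset)
    if np.any(off == 0) or np.any(np.abs(off) > L):
        raise ValidationError(f"offset out of band [-{L}, {L}] \\ {{0}}")
    return np.where(off < 0, off + L, off + L - 1).astype(int)


def column_to_offset(col, L: int):
    """Band column index -> signed nonzero offset."""
    c = np.asarray(col)
    return np.where(c < L, c - L, c - L + 1)


@dataclass
class NarrowBand:
    """The semantic-constraint sampling of an image around a prior contour."""

    points: np.ndarray  # (N, 2) prior contour
    normals: np.ndarray  # (N, 2) unit outward normals
    IM: np.ndarray  # (N, 2L, 2) sample coordinates (row, col)
    GM: np.ndarray  # (N, 2L) gray values, GM = φ(IM)
    L: int

    @property
    def n_profiles(self) -> int:
        return int(self.points.shape[0])


def build_narrowband(image, c, L: int) -> NarrowBand:
    """Sample the N×2L narrow band of normal profiles on ``image``."""
    if L < 1:
        raise ValidationError(f"band half-length L must be >= 1, got {L}")
    p = as_contour(c)
    normals = compute_normals(p)
    offs = signed_offsets(L).astype(float)
    im = p[:, None, :] + offs[None, :, None] * normals[:, None, :]
    gm = bilinear_sample(image, im.reshape(-1, 2)).reshape(p.shape[0], 2 * L)
    return NarrowBand(points=p, normals=normals, IM=im, GM=gm, L=L)


def band_to_contour(nb: NarrowBand, est) -> np.ndarray:
    """Look up the contour at integer band offsets through ``IM``."""
    offsets = np.asarray(getattr(est, "offsets", est))
    if offsets.shape[0] != nb.n_profiles:
        raise ValidationError("estimate length does not match profile count")
    cols = offset_to_column(offsets, nb.L)
    return nb.IM[np.arange(nb.n_profiles), cols]


def offsets_to_contour(nb: NarrowBand, offsets) -> np.ndarray:
    """Contour at real-valued signed offsets along the stored normals."""
    off = np.asarray(offsets, dtype=float)
    if off.shape[0] != nb.n_profiles:
        raise ValidationError("offset sequence length does not match profile count")
    if np.any(np.abs(off) > nb.L):
        raise ValidationError("offset out of band")
    return nb.points + off[:, None] * nb.normals
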