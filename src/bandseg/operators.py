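"""Boundary proposal on normal profiles via cumulative gray differences.

For a dark-inside (hypoechoic) region bounded by brighter tissue, the
boundary along a normal profile is where the outer-window gray sum most
exceeds the inner-window gray sum.  The base operator maximizes this per
profile; the neighbourhood normal vector operator (NNVO) pools the objective
over a cyclic window of adjacent profiles before maximizing, which suppresses
single-profile outliers caused by speckle or bright artifacts.

Scoring convention: at candidate offset ``i`` with window half-length ``w``
the score is ``w * (mean of the w samples just outside − mean of the w
samples just inside)``.  When both windows fit inside the band this equals
the plain sum difference; near the band ends windows are clipped and the mean
normalization keeps a constant profile scoring exactly zero everywhere.
Ties are broken toward the offset closest to zero, then toward the inside —
absent evidence, the prior contour is the best guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .narrowband import NarrowBand, column_to_offset, offset_to_column

__all__ = [
    "BoundaryEstimate",
    "cumulative_gray_difference",
    "base_operator",
    "nnvo",
]


@dataclass
class BoundaryEstimate:
    """One boundary position per normal profile, as signed band offsets."""

    offsets: np.ndarray  # (N,) signed offsets; integer from operators
    scores: np.ndarray | None = None  # (N,) achieved objective values

    def __len__(self) -> int:
        return int(self.offsets.shape[0])


def cumulative_gray_difference(
    nb: NarrowBand, k: int, i: int, half_window: int
) -> float:
    """Outer-minus-inner gray sum at offset ``i`` on profile ``k``.

    Strict form: both windows ``[i+1, i+w]`` and ``[i−w, i−1]`` (in offset
    terms; contiguous columns in the band) must lie inside the band.
    """
    w = int(half_window)
    if w < 1:
        raise ValidationError(f"half_window must be >= 1, got {w}")
    j = int(offset_to_column(i, nb.L))
    two_l = 2 * nb.L
    if j - w < 0 or j + w > two_l - 1:
        raise ValidationError(
            f"window of {w} around offset {i} exceeds the band (L={nb.L})"
        )
    profile = nb.GM[k]
    return float(np.sum(profile[j + 1 : j + w + 1]) - np.sum(profile[j - w : j]))


def _score_matrix(gm: np.ndarray, half_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores (N, n_candidates) for candidate columns 1 … 2L−2.

    score = w * (mean of clipped outer window − mean of clipped inner window).
    """
    w = int(half_window)
    if w < 1:
        raise ValidationError(f"half_window must be >= 1, got {w}")
    n, two_l = gm.shape
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(gm, axis=1)], axis=1)
    cand = np.arange(1, two_l - 1)
    scores = np.empty((n, cand.shape[0]))
    for idx, j in enumerate(cand):
        hi = min(j + w, two_l - 1)
        lo = max(j - w, 0)
        n_out = hi - j
        n_in = j - lo
        so = cs[:, hi + 1] - cs[:, j + 1]
        si = cs[:, j] - cs[:, lo]
        scores[:, idx] = w * (so / n_out - si / n_in)
    return scores, cand


def _tie_break_order(cand: np.ndarray, L: int) -> np.ndarray:
    offs = column_to_offset(cand, L)
    # preference: smallest |offset| first, inside (negative) before outside
    return np.lexsort((offs > 0, np.abs(offs)))


def _argmax_with_ties(scores: np.ndarray, cand: np.ndarray, L: int) -> np.ndarray:
    order = _tie_break_order(cand, L)
    reordered = scores[:, order]
    best = reordered.max(axis=1, keepdims=True)
    first = np.argmax(reordered == best, axis=1)
    return cand[order[first]]


def base_operator(nb: NarrowBand, half_window: int | None = None) -> BoundaryEstimate:
    """Per-profile argmax of the cumulative gray difference.

    ``half_window`` defaults to L (full half-band, windows clipped at band
    ends).
    """
    w = nb.L if half_window is None else int(half_window)
    scores, cand = _score_matrix(nb.GM, w)
    cols = _argmax_with_ties(scores, cand, nb.L)
    rows = np.arange(nb.n_profiles)
    col_idx = {c: idx for idx, c in enumerate(cand)}
    achieved = scores[rows, [col_idx[c] for c in cols]]
    return BoundaryEstimate(
        offsets=column_to_offset(cols, nb.L), scores=achieved
    )


def nnvo(
    nb: NarrowBand,
    half_window: int | None = None,
    m_left: int = 10,
    m_right: int = 5,
) -> BoundaryEstimate:
    """Neighbourhood normal vector operator.

    Maximizes the gray-difference objective summed over profiles
    ``k−m_left … k+m_right`` (cyclic) at a common offset.  Defaults
    ``m_left=10, m_right=5``.  With ``m_left = m_right = 0`` this reduces to
    the base operator.
    """
    if m_left < 0 or m_right < 0:
        raise ValidationError("neighbour window sizes must be >= 0")
    n = nb.n_profiles
    if m_left + m_right >= n:
        raise ValidationError(
            f"neighbour window ({m_left}+{m_right}) must be smaller than N={n}"
        )
    w = nb.L if half_window is None else int(half_window)
    scores, cand = _score_matrix(nb.GM, w)
    pooled = np.zeros_like(scores)
    for d in range(-m_left, m_right + 1):
        pooled += np.roll(scores, -d, axis=0)
    cols = _argmax_with_ties(pooled, cand, nb.L)
    rows = np.arange(n)
    col_idx = {c: idx for idx, c in enumerate(cand)}
    achieved = pooled[rows, [col_idx[c] for c in cols]]
    return BoundaryEstimate(offsets=column_to_offset(cols, nb.L), scores=achieved)
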