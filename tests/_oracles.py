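"""Independent brute-force oracles used to check the vectorized operators.

Everything here is written as plain Python loops from the documented
contracts, deliberately not sharing code with the package internals (beyond
the public column/offset convention, which is part of the contract).
"""

from __future__ import annotations

import numpy as np

from bandseg import NarrowBand, compute_normals


def make_random_band(rng: np.random.Generator, n_max: int = 20, l_max: int = 6):
    """A synthetic narrow band with integer-valued gray samples.

    Points sit on a circle so normals are well defined; GM is random uint8,
    which makes the score arithmetic exactly reproducible in float.
    """
    n = int(rng.integers(3, n_max + 1))
    L = int(rng.integers(2, l_max + 1))
    t = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([50 + 40 * np.sin(t), 50 + 40 * np.cos(t)])
    normals = compute_normals(pts)
    offs = np.concatenate([np.arange(-L, 0), np.arange(1, L + 1)]).astype(float)
    im = pts[:, None, :] + offs[None, :, None] * normals[:, None, :]
    gm = rng.integers(0, 256, size=(n, 2 * L)).astype(float)
    return NarrowBand(points=pts, normals=normals, IM=im, GM=gm, L=L)


def score_brute(gm_row: np.ndarray, j: int, w: int) -> float:
    """Clipped-window outer-minus-inner score at band column ``j``.

    score = w * (mean of samples j+1 … min(j+w, 2L−1) − mean of samples
    max(j−w, 0) … j−1); both windows are nonempty for j in 1 … 2L−2.
    """
    two_l = gm_row.shape[0]
    hi = min(j + w, two_l - 1)
    lo = max(j - w, 0)
    n_out = hi - j
    n_in = j - lo
    so = float(np.sum(gm_row[j + 1 : hi + 1]))
    si = float(np.sum(gm_row[lo:j]))
    return w * (so / n_out - si / n_in)


def _col_to_off(c: int, L: int) -> int:
    return c - L if c < L else c - L + 1


def _tie_sorted_columns(L: int):
    """Candidate columns 1 … 2L−2 in tie-break preference order.

    Preference: smallest |offset| first; at equal |offset| the inside
    (negative) candidate comes first.
    """
    cand = list(range(1, 2 * L - 1))
    return sorted(cand, key=lambda c: (abs(_col_to_off(c, L)), _col_to_off(c, L) > 0))


def argmax_brute(scores_per_col: dict, L: int) -> int:
    """First strict maximum over candidates visited in tie-break order."""
    best_col, best = None, -np.inf
    for c in _tie_sorted_columns(L):
        s = scores_per_col[c]
        if s > best:
            best, best_col = s, c
    return _col_to_off(best_col, L)


def base_operator_brute(nb: NarrowBand, w: int) -> np.ndarray:
    out = []
    for k in range(nb.n_profiles):
        per_col = {j: score_brute(nb.GM[k], j, w) for j in range(1, 2 * nb.L - 1)}
        out.append(argmax_brute(per_col, nb.L))
    return np.asarray(out)


def nnvo_brute(nb: NarrowBand, w: int, m_left: int, m_right: int) -> np.ndarray:
    n = nb.n_profiles
    single = [
        {j: score_brute(nb.GM[k], j, w) for j in range(1, 2 * nb.L - 1)}
        for k in range(n)
    ]
    out = []
    for k in range(n):
        pooled = {}
        for j in range(1, 2 * nb.L - 1):
            acc = 0.0
            # same accumulation order as the implementation, for bitwise equality
            for d in range(-m_left, m_right + 1):
                acc += single[(k + d) % n][j]
            pooled[j] = acc
        out.append(argmax_brute(pooled, nb.L))
    return np.asarray(out)


def fixed_lambda_weights(lam: float, k: int) -> np.ndarray:
    """Closed-form ETSD weight vector for constant decay at output index k.

    With zero initialization and bias correction, output_k = Σ_j w_j x_j with
    w_j = (1−λ) λ^{k−j} / (1 − λ^{k+1}),  j = 0 … k.
    """
    j = np.arange(k + 1)
    return (1.0 - lam) * lam ** (k - j) / (1.0 - lam ** (k + 1))
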