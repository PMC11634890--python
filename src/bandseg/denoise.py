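"""Bidirectional exponential time-series denoising of boundary offsets.

The per-profile boundary offsets around a closed contour form a sequence in
which true anatomy varies slowly while operator failures appear as jumps.
They are smoothed by a bias-corrected exponentially weighted moving average
whose decay factor ramps up over iteration rounds, then fused with the raw
offsets: points whose reconstructed contour turns sharply (curvature above a
threshold) are treated as anomalies and pulled toward the smoothed value,
everything else keeps most of its raw evidence.  A second pass runs the same
machinery backward over the sequence so both ends of the contour benefit from
context.

The smoother keeps an accumulator ``m_k = λ_k m_{k−1} + (1−λ_k) x_k`` with
``m_0 = 0`` and divides by ``1 − Π_{j≤k} λ_j``.  For constant λ the normalizer
reduces to the familiar ``1 − λ^k`` and the first output equals the first
input; for any schedule the output is an exact convex combination of the
prefix inputs, hence range-bounded and constant-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .narrowband import NarrowBand, offsets_to_contour
from .operators import BoundaryEstimate

__all__ = [
    "EtsdParams",
    "lambda_schedule",
    "etsd_forward",
    "etsd_backward",
    "curvature",
    "detect_outliers",
    "fuse",
    "bidirectional_denoise",
]


@dataclass
class EtsdParams:
    """Tunables of the denoiser.

    lambda0: cap of the decay schedule, in (0, 1).  The effective decay is
        ``min(lambda0, (1+k)/(10+k))`` at round k, so early samples are
        weighted lightly while the data history is short.
    alpha: fusion weight in (0, 1); normal points keep ``alpha`` of the raw
        offset, anomalous points keep only ``1 − alpha``.
    curvature_threshold: |turning angle| (radians) above which a contour
        point is flagged anomalous.
    k_step: neighbour stride used when measuring the turning angle.
    """

    lambda0: float = 0.9
    alpha: float = 0.9
    curvature_threshold: float = np.pi / 4
    k_step: int = 1

    def __post_init__(self):
        if not (0.0 < self.lambda0 < 1.0):
            raise ValidationError(f"lambda0 must be in (0, 1), got {self.lambda0}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.curvature_threshold > 0:
            raise ValidationError("curvature_threshold must be positive")
        if self.k_step < 1:
            raise ValidationError("k_step must be >= 1")


def lambda_schedule(lambda0: float, k: int) -> float:
    """Decay factor at round ``k``: ``min(lambda0, (1+k)/(10+k))``."""
    if k < 1:
        raise ValidationError(f"iteration round must be >= 1, got {k}")
    if not (0.0 < lambda0 < 1.0):
        raise ValidationError(f"lambda0 must be in (0, 1), got {lambda0}")
    return min(lambda0, (1.0 + k) / (10.0 + k))


def etsd_forward(seq, params: EtsdParams, dynamic: bool = True) -> np.ndarray:
    """Bias-corrected exponential smoothing, front to back.

    With ``dynamic=False`` the decay is held at ``params.lambda0`` (useful for
    checking against the closed-form fixed-λ weight vector).
    """
    x = np.asarray(seq, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("empty sequence")
    out = np.empty_like(x)
    m = 0.0
    prod = 1.0
    for k in range(1, x.size + 1):
        lam = lambda_schedule(params.lambda0, k) if dynamic else params.lambda0
        m = lam * m + (1.0 - lam) * x[k - 1]
        prod *= lam
        out[k - 1] = m / (1.0 - prod)
    return out


def etsd_backward(first_pass, params: EtsdParams, dynamic: bool = True) -> np.ndarray:
    """Second-round smoothing: forward pass over the reversed sequence."""
    x = np.asarray(first_pass, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("empty sequence")
    return etsd_forward(x[::-1], params, dynamic=dynamic)[::-1]


def curvature(points, k_step: int = 1) -> np.ndarray:
    """Turning angle at each contour point, wrapped to (−π, π].

    ``θ_i = atan2(y_{i+k}−y_i, x_{i+k}−x_i) − atan2(y_i−y_{i−k}, x_i−x_{i−k})``
    with cyclic indexing and x = col, y = row.
    """
    if k_step < 1:
        raise ValidationError(f"k_step must be >= 1, got {k_step}")
    p = np.asarray(points, dtype=float)
    fwd = np.roll(p, -k_step, axis=0) - p
    bwd = p - np.roll(p, k_step, axis=0)
    if np.any(np.all(fwd == 0, axis=1)) or np.any(np.all(bwd == 0, axis=1)):
        raise ValidationError("coincident points in a curvature triple")
    ang_f = np.arctan2(fwd[:, 0], fwd[:, 1])  # y = row, x = col
    ang_b = np.arctan2(bwd[:, 0], bwd[:, 1])
    theta = np.remainder(ang_f - ang_b, 2.0 * np.pi)
    theta[theta > np.pi] -= 2.0 * np.pi
    return theta


def detect_outliers(points, params: EtsdParams, k_step: int | None = None) -> np.ndarray:
    """Boolean anomaly mask: |turning angle| above the curvature threshold."""
    step = params.k_step if k_step is None else k_step
    theta = curvature(points, step)
    return np.abs(theta) > params.curvature_threshold


def fuse(raw, smooth, mask, alpha: float) -> np.ndarray:
    """Weighted fusion of raw and smoothed offsets.

    Normal points: ``α·raw + (1−α)·smooth`` (raw evidence dominates).
    Anomalous points: ``(1−α)·raw + α·smooth`` (pulled to the trend).
    """
    r = np.asarray(raw, dtype=float).ravel()
    s = np.asarray(smooth, dtype=float).ravel()
    m = np.asarray(mask, dtype=bool).ravel()
    if not (r.shape == s.shape == m.shape):
        raise ValidationError("raw, smooth and mask must have equal lengths")
    normal = alpha * r + (1.0 - alpha) * s
    abnormal = (1.0 - alpha) * r + alpha * s
    return np.where(m, abnormal, normal)


@dataclass
class DenoiseDiagnostics:
    forward_smoothed: np.ndarray
    mask_round1: np.ndarray
    fused_round1: np.ndarray
    backward_smoothed: np.ndarray
    mask_round2: np.ndarray


def bidirectional_denoise(
    est: BoundaryEstimate,
    nb: NarrowBand,
    params: EtsdParams | None = None,
    full_output: bool = False,
):
    """Two-round smoothing of a boundary estimate.

    Round 1: forward smoothing of the offset sequence, curvature-based
    anomaly detection on the reconstructed contour, weighted fusion.
    Round 2: backward smoothing of the round-1 result, detection, fusion.
    The closed contour is treated as an open sequence per pass, starting at
    profile 0 (fixed by the resampling convention).  Final offsets are kept
    within the band.
    """
    params = params or EtsdParams()
    raw = np.asarray(est.offsets, dtype=float)
    if raw.size == 0:
        raise ValidationError("empty boundary estimate")

    smooth1 = etsd_forward(raw, params)
    mask1 = detect_outliers(offsets_to_contour(nb, raw), params)
    fused1 = fuse(raw, smooth1, mask1, params.alpha)

    smooth2 = etsd_backward(fused1, params)
    mask2 = detect_outliers(offsets_to_contour(nb, np.clip(fused1, -nb.L, nb.L)), params)
    fused2 = fuse(fused1, smooth2, mask2, params.alpha)

    final = np.clip(fused2, -nb.L, nb.L)
    result = BoundaryEstimate(offsets=final, scores=est.scores)
    if full_output:
        return result, DenoiseDiagnostics(
            forward_smoothed=smooth1,
            mask_round1=mask1,
            fused_round1=fused1,
            backward_smoothed=smooth2,
            mask_round2=mask2,
        )
    return result
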