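"""Point distribution model: Procrustes alignment, PCA shape space.

The statistical shape prior is built from a set of corresponded training
contours.  Generalized Procrustes analysis removes pose (translation,
rotation, isotropic scale), then principal component analysis of the aligned
landmark vectors yields a mean shape x̄ and an orthonormal basis P of modes of
variation; any shape in the span is ``x̄ + P s`` with coefficients
``s = Pᵀ (x − x̄)``.

Conventions (documented deliberately, since texts differ):

* The covariance is the biased ``1/n`` scatter matrix.
* The retained mode count ``t`` is the smallest count whose cumulative
  eigenvalue fraction strictly exceeds the retained-variance target ``mu``
  (default 0.95, the low end of the conventional 95–98 % range).
* Procrustes weights are uniform and no tangent-space projection is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import ValidationError
from .contour import as_contour

__all__ = [
    "SimilarityTransform",
    "ProcrustesResult",
    "ShapeModel",
    "procrustes_align",
    "fit_point_distribution_model",
    "reconstruct_shape",
    "project_shape",
]


@dataclass
class SimilarityTransform:
    """Map ``x -> scale * (x @ rotation) + translation`` on (N, 2) points."""

    scale: float
    rotation: np.ndarray  # (2, 2), det = +1
    translation: np.ndarray  # (2,)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return self.scale * (p @ self.rotation) + self.translation

    @property
    def is_identity(self) -> bool:
        return (
            np.isclose(self.scale, 1.0)
            and np.allclose(self.rotation, np.eye(2))
            and np.allclose(self.translation, 0.0)
        )


@dataclass
class ProcrustesResult:
    aligned: list  # list of (N, 2) arrays
    transforms: list  # list of SimilarityTransform (input -> aligned)
    residuals: np.ndarray  # per-iteration sum of squared distances to the mean
    mean: np.ndarray  # (N, 2), zero centroid, unit centroid size

    def __iter__(self):  # allow ``aligned, transforms = procrustes_align(...)``
        return iter((self.aligned, self.transforms))


def _check_shapes(shapes):
    if len(shapes) == 0:
        raise ValidationError("no shapes given")
    arrs = []
    n0 = None
    for idx, s in enumerate(shapes):
        a = as_contour(s)
        if n0 is None:
            n0 = a.shape[0]
        elif a.shape[0] != n0:
            raise ValidationError(
                f"shape {idx} has {a.shape[0]} points, expected {n0}"
            )
        if np.allclose(a, a[0]):
            raise ValidationError(f"shape {idx} is degenerate (all points coincide)")
        arrs.append(a)
    return arrs


def _normalize(p):
    """Center to zero centroid and scale to unit centroid size (Frobenius)."""
    c = p.mean(axis=0)
    q = p - c
    size = np.linalg.norm(q)
    if size == 0:
        raise ValidationError("degenerate shape: zero centroid size")
    return q / size, c, size


def _orthogonal_fit(x, target):
    """Optimal rotation (det +1) and scale mapping unit-norm ``x`` onto ``target``."""
    m = x.T @ target
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    sgn = np.ones(2)
    sgn[-1] = d
    rot = (u * sgn) @ vt
    scale = float(np.sum(s * sgn))  # trace of the corrected singular spectrum
    return rot, scale


def procrustes_align(shapes, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes alignment of corresponded contours.

    All shapes are similarity-transformed (rotation + isotropic scale +
    translation, uniform point weights) so as to minimize the summed squared
    distance to the evolving mean; the mean is renormalized to zero centroid
    and unit centroid size each round.  The residual sum is non-increasing
    across iterations; iteration stops when its decrease falls below ``tol``.
    """
    arrs = _check_shapes(shapes)
    norm = [_normalize(a) for a in arrs]
    aligned = [n[0] for n in norm]
    rots = [np.eye(2) for _ in arrs]
    scales = [1.0 for _ in arrs]

    residuals = []
    prev = np.inf
    for _ in range(max_iter):
        mean = np.mean(aligned, axis=0)
        mean, _, _ = _normalize(mean)
        new_aligned = []
        for i, (base, _, _) in enumerate(norm):
            rot, scale = _orthogonal_fit(base, mean)
            rots[i] = rot
            scales[i] = scale
            new_aligned.append(scale * (base @ rot))
        aligned = new_aligned
        res = float(sum(np.sum((a - mean) ** 2) for a in aligned))
        residuals.append(res)
        if prev - res < tol:
            break
        prev = res

    transforms = []
    for (base, cen, size), rot, scale in zip(norm, rots, scales):
        s = scale / size
        t = -s * (cen @ rot)
        transforms.append(SimilarityTransform(scale=s, rotation=rot, translation=t))
    return ProcrustesResult(
        aligned=aligned,
        transforms=transforms,
        residuals=np.asarray(residuals),
        mean=mean,
    )


@dataclass
class ShapeModel:
    """PCA shape space: mean landmark vector plus retained eigenmodes."""

    mean_shape: np.ndarray  # (2N,) flattened (row, col) pairs
    eigenvectors: np.ndarray  # (2N, t), orthonormal columns
    eigenvalues: np.ndarray  # (t,), descending, positive
    variance_fraction: float  # retained-variance target mu
    n_points: int
    total_variance: float = field(default=0.0)  # trace of the covariance

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.shape[0])

    @property
    def mean_contour(self) -> np.ndarray:
        return self.mean_shape.reshape(self.n_points, 2)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean_shape": self.mean_shape.tolist(),
                    "eigenvectors": self.eigenvectors.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "variance_fraction": self.variance_fraction,
                    "n_points": self.n_points,
                    "total_variance": self.total_variance,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "ShapeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean_shape=np.asarray(d["mean_shape"], dtype=float),
            eigenvectors=np.asarray(d["eigenvectors"], dtype=float).reshape(
                len(d["mean_shape"]), -1
            ),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            variance_fraction=float(d["variance_fraction"]),
            n_points=int(d["n_points"]),
            total_variance=float(d.get("total_variance", 0.0)),
        )


def fit_point_distribution_model(aligned, mu: float = 0.95) -> ShapeModel:
    """Fit the PCA shape space from aligned contours.

    The mean is the arithmetic landmark mean, the covariance the biased
    ``1/n`` scatter matrix, and the smallest t with cumulative eigenvalue
    fraction strictly above ``mu`` modes are retained.
    """
    if not (0.0 < mu < 1.0):
        raise ValidationError(f"mu must be in (0, 1), got {mu}")
    arrs = _check_shapes(aligned)
    if len(arrs) < 2:
        raise ValidationError("need at least 2 shapes to fit a model")
    n_points = arrs[0].shape[0]
    x = np.stack([a.ravel() for a in arrs])  # (n, 2N)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / x.shape[0]

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    total = float(np.sum(evals))
    if total <= 0.0:
        t = 0
    else:
        frac = np.cumsum(evals) / total
        t = int(np.searchsorted(frac, mu, side="right") + 1)
        t = min(t, evals.shape[0])
    return ShapeModel(
        mean_shape=mean,
        eigenvectors=evecs[:, :t].copy(),
        eigenvalues=evals[:t].copy(),
        variance_fraction=mu,
        n_points=n_points,
        total_variance=total,
    )


def reconstruct_shape(model: ShapeModel, s) -> np.ndarray:
    """Instantiate the shape ``x̄ + P s`` as an (N, 2) contour."""
    s = np.asarray(s, dtype=float).ravel()
    if s.shape[0] != model.n_modes:
        raise ValidationError(
            f"coefficient vector has length {s.shape[0]}, model has {model.n_modes} modes"
        )
    x = model.mean_shape + model.eigenvectors @ s
    return x.reshape(model.n_points, 2)


def project_shape(model: ShapeModel, x) -> np.ndarray:
    """Shape coefficients ``Pᵀ (x − x̄)`` of a contour in the model basis."""
    arr = as_contour(x)
    if arr.shape[0] != model.n_points:
        raise ValidationError(
            f"contour has {arr.shape[0]} points, model expects {model.n_points}"
        )
    return model.eigenvectors.T @ (arr.ravel() - model.mean_shape)
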