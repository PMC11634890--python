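"""Synthetic ultrasound-like phantoms with exact ground truth.

The generator emulates the gross appearance of a transrectal ultrasound
image of a hypoechoic gland: a roughly elliptical dark region with a smooth
star-convex boundary (radial Fourier harmonics around a mean radius), bright
surrounding tissue, fully-developed multiplicative speckle (unit-mean gamma
noise followed by Gaussian blur), wedge-shaped shadow artifacts crossing the
boundary, and localized bright patches just inside the boundary that flip
local contrast and induce boundary-search outliers.  Every phantom carries
its exact ground-truth contour and mask, so segmentation error is measurable
to the pixel.

It is a statistical stand-in, not a physical simulation: there is no wave
propagation, depth-dependent attenuation, or transducer geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._errors import ValidationError
from .contour import ensure_ccw

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "generate_shape_family",
    "apply_speckle",
    "make_suite",
    "clean_spec",
]


@dataclass
class PhantomSpec:
    """Generation parameters; defaults give a moderately noisy phantom.

    ``fourier_amplitudes`` are relative radial perturbations on harmonics
    2, 3, … with random phases; their sum must stay below 1 so the radial
    function is positive (star-convex boundary).
    """

    image_size: tuple = (576, 768)  # (H, W)
    center: tuple | None = None  # (row, col); None = image center
    mean_radius: float = 140.0
    fourier_amplitudes: tuple = (0.04, 0.02, 0.01)
    inside_level: float = 60.0
    outside_level: float = 150.0
    speckle_shape: float | None = 0.35  # gamma shape of raw grains; None disables
    speckle_grain: float = 2.5  # correlation length (px) of the speckle field
    blur_sigma: float = 1.5
    n_shadow_wedges: int = 2
    shadow_strength: float = 0.70
    n_noise_patches: int = 6
    n_contour_points: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.inside_level < self.outside_level:
            raise ValidationError("inside_level must be below outside_level (hypoechoic)")
        if not self.mean_radius > 0:
            raise ValidationError("mean_radius must be positive")
        if sum(abs(a) for a in self.fourier_amplitudes) >= 1.0:
            raise ValidationError(
                "harmonic amplitudes sum to >= 1: radial function not guaranteed positive"
            )

    @property
    def resolved_center(self) -> tuple:
        if self.center is not None:
            return tuple(self.center)
        h, w = self.image_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass
class Phantom:
    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (H, W) bool ground truth
    contour: np.ndarray  # (N, 2) ground-truth boundary points, CCW
    spec: PhantomSpec = field(repr=False)
    seed: int = 0


def _radial(theta, mean_radius, amplitudes, phases):
    r = np.ones_like(theta)
    for h, (a, ph) in enumerate(zip(amplitudes, phases), start=2):
        r = r + a * np.cos(h * theta + ph)
    return mean_radius * r


def apply_speckle(
    image, shape_param: float, rng: np.random.Generator, grain: float = 0.0
) -> np.ndarray:
    """Multiply by unit-mean gamma noise (fully-developed speckle model).

    ``grain`` > 0 low-pass filters the noise field to that correlation
    length in pixels, emulating the finite point-spread function that gives
    real speckle its granular texture; linear filtering preserves the unit
    mean.
    """
    if not shape_param > 0:
        raise ValidationError("gamma shape parameter must be positive")
    img = np.asarray(image, dtype=float)
    noise = rng.gamma(shape_param, 1.0 / shape_param, img.shape)
    if grain and grain > 0:
        noise = ndimage.gaussian_filter(noise, grain)
    return img * noise


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom; bit-deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cr, cc = spec.resolved_center
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.fourier_amplitudes))

    theta_min_check = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    if np.min(_radial(theta_min_check, spec.mean_radius, spec.fourier_amplitudes, phases)) <= 0:
        raise ValidationError("radial function not positive: non-star-convex spec")

    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - cr
    dc = cols - cc
    theta = np.arctan2(dr, dc)
    rad = np.hypot(dr, dc)
    r_bound = _radial(theta, spec.mean_radius, spec.fourier_amplitudes, phases)
    mask = rad <= r_bound

    n = spec.n_contour_points
    tk = 2.0 * np.pi * np.arange(n) / n
    rk = _radial(tk, spec.mean_radius, spec.fourier_amplitudes, phases)
    contour = ensure_ccw(
        np.column_stack([cr + rk * np.sin(tk), cc + rk * np.cos(tk)])
    )

    img = np.where(mask, spec.inside_level, spec.outside_level).astype(float)

    # wedge-shaped shadow artifacts crossing the boundary
    for _ in range(spec.n_shadow_wedges):
        psi = rng.uniform(0.0, 2.0 * np.pi)
        width = rng.uniform(0.25, 0.45)
        r_in = 0.55 * spec.mean_radius
        r_out = 2.2 * spec.mean_radius
        dtheta = np.angle(np.exp(1j * (theta - psi)))
        wedge = (np.abs(dtheta) < width / 2.0) & (rad >= r_in) & (rad <= r_out)
        img[wedge] *= spec.shadow_strength

    # bright patches just inside the boundary (local contrast flips)
    for _ in range(spec.n_noise_patches):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rb = _radial(np.array([ang]), spec.mean_radius, spec.fourier_amplitudes, phases)[0]
        depth = rng.uniform(3.0, 10.0)
        pr = cr + (rb - depth) * np.sin(ang)
        pc = cc + (rb - depth) * np.cos(ang)
        # width mixture: narrow specks corrupt one profile, wide patches several
        sigma = rng.uniform(1.5, 9.0)
        amp = (spec.outside_level - spec.inside_level) * rng.uniform(1.3, 2.2)
        d2 = (rows - pr) ** 2 + (cols - pc) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma**2))

    if spec.speckle_shape:
        img = apply_speckle(img, spec.speckle_shape, rng, grain=spec.speckle_grain)
    if spec.blur_sigma and spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Phantom(image=image, mask=mask, contour=contour, spec=spec, seed=spec.seed)


def generate_shape_family(
    n: int,
    base: PhantomSpec,
    mode_sds,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> list:
    """Draw ``n`` contours from a generative shape model.

    The base contour comes from the spec's radial function; each of the
    stated modes is a radial-displacement field on one harmonic (starting at
    harmonic 2), orthonormalized, and shapes are base plus Gaussian
    coefficients with the given standard deviations (pixels) plus isotropic
    landmark noise of ``noise_sd`` px.  The planted mode count is recoverable
    by ``fit_point_distribution_model``.
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 shapes, got {n}")
    rng = np.random.default_rng(seed)
    cr, cc = base.resolved_center
    n_pts = base.n_contour_points
    tk = 2.0 * np.pi * np.arange(n_pts) / n_pts
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(base.fourier_amplitudes))
    rk = _radial(tk, base.mean_radius, base.fourier_amplitudes, phases)
    base_contour = np.column_stack([cr + rk * np.sin(tk), cc + rk * np.cos(tk)])
    radial_dir = np.column_stack([np.sin(tk), np.cos(tk)])  # unit (row, col)

    sds = np.asarray(mode_sds, dtype=float)
    modes = np.stack(
        [(np.cos((2 + j) * tk)[:, None] * radial_dir).ravel() for j in range(sds.size)],
        axis=1,
    )  # (2N, n_modes)
    q, _ = np.linalg.qr(modes)

    shapes = []
    for _ in range(n):
        z = rng.normal(size=sds.size) * sds
        x = base_contour.ravel() + q @ z
        x = x + rng.normal(scale=noise_sd, size=x.shape)
        shapes.append(x.reshape(n_pts, 2))
    return shapes


def clean_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A noise-free phantom spec: no speckle, wedges or patches, mild blur."""
    kwargs = dict(
        speckle_shape=None,
        blur_sigma=1.0,
        n_shadow_wedges=0,
        n_noise_patches=0,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def make_suite(n: int = 20, seed: int = 0, noisy: bool = True) -> list:
    """A reproducible suite of phantoms with varied pose, size and shape.

    Centers are jittered by up to ±30 px and mean radii drawn from
    [120, 155] px so that localization is actually exercised.
    """
    if n < 1:
        raise ValidationError("suite size must be >= 1")
    rng = np.random.default_rng(seed)
    phantoms = []
    base = PhantomSpec() if noisy else clean_spec()
    h, w = base.image_size
    for i in range(n):
        jitter = rng.uniform(-30.0, 30.0, size=2)
        center = ((h - 1) / 2.0 + jitter[0], (w - 1) / 2.0 + jitter[1])
        radius = rng.uniform(120.0, 155.0)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, center=center, mean_radius=radius, seed=sub_seed)
        phantoms.append(generate_phantom(spec))
    return phantoms
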