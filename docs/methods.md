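# Methods and conventions

This note records the mathematical conventions, parameter choices and known
limitations of the implementation.  Everything stated here is either a
definition or a property checked by the test suite; run
`python scripts/acceptance.py` for the measured numbers on your machine.

## Coordinates and contours

Images are `(H, W)` arrays indexed `(row, col)`, pixel centers at integer
coordinates.  A contour is an `(N, 2)` float array of `(row, col)` points
describing a closed polygon (closing edge implicit).  Contours are stored
counter-clockwise, defined as positive shoelace area with `x = col`,
`y = row`; inputs are re-oriented on load with the starting point preserved.
Resampling to N points is done at uniform arc length starting from point 0,
which fixes the sequence start used by the smoothing stage.

## Shape model

* Generalized Procrustes alignment: uniform landmark weights, similarity
  transforms (rotation with det +1, isotropic scale, translation), mean
  renormalized to zero centroid and unit centroid size (Frobenius norm) each
  round.  No tangent-space projection is applied.  The residual sum is
  non-increasing (asserted in tests).
* PCA over the aligned `2N`-vectors with the **biased `1/n` covariance**.
  The retained mode count `t` is the smallest count whose cumulative
  eigenvalue fraction strictly exceeds the retention target `μ` (default
  0.95).  Texts differ on both conventions; these are fixed here and tested.
* Zero-variance training sets produce a valid model with `t = 0`.

## Transform localization

The prior placement is the affine `col' = t1·col + tx`, `row' = t2·row + ty`
(homogeneous matrix acting on `[col, row, 1]`).  There is deliberately no
rotation parameter: moderate rotation is absorbed by the shape modes and the
band search.  A learned localizer can be plugged in by supplying the four
parameters directly; the built-in, training-free default estimates them from
image moments:

1. Smooth with a Gaussian (σ = 6 px), invert (the target is dark), threshold
   by Otsu, and weight each pixel by the **squared** above-threshold excess.
2. Re-estimate the weighted centroid and second moments three times, each
   time trimming weights outside 1.5× the current 2σ extent ellipse.  This
   suppresses shadow wedges and other dark-outside structure attached to the
   target, which otherwise inflate the scale estimate.
3. Match `2σ` of the trimmed weights against the mean shape's half-extents.
   The squared-excess weighting tapers at the blurred boundary and shrinks
   second moments by about 5% (measured on clean phantoms before any
   acceptance testing); a fixed `scale_correction = 1.05` compensates.

The pipeline does not require this initializer to be accurate — the
acceptance suite perturbs the placement by L/2 px and requires the suite-mean
Dice to move by at most 0.02.

## Narrow band

At each prior point, samples are taken along the outward unit normal
(cyclic central-difference tangent rotated 90°, oriented away from the
centroid) at signed offsets −L…−1, +1…+L — the point itself is excluded, so a
profile has exactly 2L entries ordered inside→outside.  Column mapping:
offset `o` occupies band column `o+L` if `o<0` else `o+L−1`.  Sampling is
bilinear with coordinates clamped to the image border (a band straddling the
border sees the border value, not zeros; this deviation from zero-padding is
deliberate so border profiles remain informative).

## Boundary operators

At candidate offset `i` with window half-length `w` (default `w = L`) the
score is `w · (mean of the ≤w samples just outside − mean of the ≤w samples
just inside)`, windows clipped at the band ends.  When both windows fit this
equals the plain cumulative sum difference; the mean normalization makes a
constant profile score exactly zero everywhere.  Candidates are the 2L−2
interior columns.  Ties break toward the smallest |offset|, inside before
outside — absent evidence, stay near the prior.  A strict (unclipped)
variant of the score is exposed for single offsets and raises when the
window leaves the band.

NNVO pools the per-profile score matrix over a cyclic profile window
`k−m_left … k+m_right` (defaults 10 and 5) at a common offset before the
argmax.  Both operators are verified **exactly** (bitwise, on integer-valued
bands) against an independent brute-force implementation.

The pooling assumption is that the prior-to-truth offset varies slowly along
the contour.  Its corollary is a deterministic smoothing bias: with an
imperfect prior the pooled estimate lags offset variation by a couple of
pixels *even on noise-free images* (the asymmetric 10+5 window makes the lag
directional).  Tests assert that with an exactly placed prior all ablation
variants agree within 1 px mean error on clean images, and within 3 px end
to end.

## Exponential time-series denoising

The smoother keeps an accumulator `m_k = λ_k m_{k−1} + (1−λ_k) x_k` with
`m_0 = 0` and outputs `m_k / (1 − Π_{j≤k} λ_j)`; the decay schedule is
`λ_k = min(λ₀, (1+k)/(10+k))` with λ₀ = 0.9.  The output is an exact convex
combination of the prefix inputs — range-bounded and constant-preserving —
and for constant λ it equals the normalized exponential weight vector
`(1−λ)λ^{k−j}/(1−λ^{k+1})` (both properties tested to 1e−10).  The backward
pass is the forward pass on the reversed sequence.

Anomaly detection measures the turning angle
`θ_i = atan2(Δy_fwd, Δx_fwd) − atan2(Δy_bwd, Δx_bwd)` (x = col, y = row,
cyclic neighbours, wrapped to (−π, π]); a regular n-gon gives exactly 2π/n.
Points with |θ| > π/4 are anomalous.  Fusion keeps `α = 0.9` of the raw
offset for normal points and `1−α` for anomalous ones.  Round 1 detects on
the raw-offset contour, round 2 on the round-1 result; final offsets are
clipped to ±L.  The closed contour is treated as an open sequence per pass,
anchored at profile 0 by the resampling convention.

## Metrics

Mean-AD/Max-AD are point-to-point distances after a fixed correspondence
rule: orient both contours CCW, resample to the larger point count at
uniform arc length, roll the truth so its start is nearest the prediction's
start.  Multiplying by `pixel_spacing` yields mm.  Overlap metrics come from
the confusion counts: Dice = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN),
FPR = FP/(FP+TN), with the identity IoU = Dice/(2−Dice) tested to 1e−12.
Conventions: two empty masks score Dice = IoU = 1; FPR with no true
negatives is 0.  Rasterization uses pixel-center point-in-polygon;
self-intersecting contours are rejected unless explicitly allowed (the
pipeline allows them for its own output, which may self-touch at band edges).

## Phantom generator

A statistical stand-in for TRUS appearance, not a physical simulation: no
wave propagation, depth-dependent attenuation or transducer geometry.
Components, applied in order to a 576×768 canvas:

* Star-convex boundary: radius `R(θ) = R₀(1 + Σ aₕ cos(hθ + φₕ))`,
  harmonics h = 2…4, amplitudes (0.04, 0.02, 0.01), random phases.  The ≤7%
  radial perturbation models a smooth gland capsule — the slowly varying
  regime the pooled operator is designed for.
* Hypoechoic interior 60, exterior 150 (8-bit scale).
* Two wedge shadows (angular width 0.25–0.45 rad, radial span 0.55R–2.2R,
  ×0.70 attenuation) crossing the boundary — the classic missing-edge
  artifact.
* Six bright Gaussian patches just inside the boundary (width σ ∈ U(1.5, 9),
  amplitude 1.3–2.2× the inside/outside contrast, 3–10 px deep), a mixture
  of single-profile outliers (for the denoiser) and multi-profile bright
  regions (for the pooling).
* Fully developed speckle: unit-mean multiplicative gamma noise (shape
  0.35), low-pass filtered to a 2.5 px correlation length.  The correlation
  emulates the point-spread-function grain of real speckle; linear filtering
  preserves the unit mean (tested: pre-blur mean within 3% over 20 seeds).
  Pixel-independent noise would be unrealistically easy, since 30-px operator
  windows average it away.
* Gaussian blur σ = 1.5, rounding, clipping to uint8.

These defaults were chosen once as a moderately noisy operating point and
then frozen; they are the study conditions for all reported suites.  Suites
jitter the center by ±30 px and draw R₀ from [120, 155] px so localization
is actually exercised.  Every phantom carries its exact boundary contour and
mask (consistency Dice > 0.99, area agreement within 2%, both tested).

## Default parameters

| parameter | value | role |
|---|---|---|
| N | 100 | contour points / normal profiles |
| L | 30 | band half-length (px) |
| half_window | L | operator window half-length |
| m_left / m_right | 10 / 5 | NNVO pooling window |
| λ₀ | 0.9 | smoothing decay cap |
| α | 0.9 | fusion weight |
| curvature threshold | π/4 | anomaly flag |
| μ | 0.95 | retained-variance target |

## Limitations

* The target must be star-convex-ish and darker than its surroundings; the
  band search cannot recover boundaries farther than L px from the prior.
* No rotation in the placement affine; strongly rotated anisotropic shapes
  rely on the shape modes.
* The asymmetric pooling window introduces a directional lag of a few pixels
  where the true offset changes quickly (see above).
* The moment initializer assumes a single dominant dark region; multiple
  dark objects of comparable size would confuse it.
* The phantom generator's realism is statistical only; results on it do not
  transfer quantitatively to clinical data.
* 2-D single-image segmentation only: no volumes, no temporal tracking.
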