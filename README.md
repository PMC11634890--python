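# bandseg

Narrow-band, shape-prior boundary segmentation for noisy 2-D ultrasound
images, with a synthetic-phantom test bed.

Ultrasound images of a hypoechoic organ (for example the prostate in
transrectal ultrasound) show a dark region with a smooth boundary buried in
multiplicative speckle, attenuation shadows and local bright artifacts.
Pixel-level classifiers struggle because the boundary evidence is weak and
frequently missing.  This package implements a three-phase approach that
leans on what is known about the anatomy instead:

1. **Shape prior and placement.**  A point distribution model (generalized
   Procrustes alignment + PCA over corresponded landmark contours) describes
   plausible organ shapes.  An affine *transform localization* — translation
   plus axis-aligned scales, estimated from image moments of the dark target
   region — places the mean shape on the image.  The placement only needs to
   be roughly right: everything downstream searches a band around it.
2. **Narrow band and boundary proposal.**  At each of the N prior-contour
   points, 2L pixels are sampled along the outward normal (bilinear
   interpolation, unit spacing, offsets −L…−1 and +1…+L).  On each profile
   the boundary is proposed where the cumulative gray difference — outer
   window minus inner window — is maximal, since the inside is dark and the
   outside bright.  The *neighbourhood normal vector operator* (NNVO) pools
   this objective over a cyclic window of adjacent profiles (default 10 left,
   5 right) before maximizing, which suppresses single-profile failures
   caused by speckle or bright patches.
3. **Bidirectional smoothing and outlier repair.**  The proposed offsets form
   a sequence around the contour in which anatomy varies slowly and failures
   are jumps.  A bias-corrected exponentially weighted moving average (decay
   `min(λ₀, (1+k)/(10+k))`, λ₀ = 0.9) smooths the sequence forward and then
   backward; points where the reconstructed contour turns sharper than π/4
   are flagged as anomalies and pulled toward the smoothed trend, all others
   keep most of their raw evidence (fusion weight α = 0.9).

Because clinical images cannot be bundled, the package ships a phantom
generator that produces ultrasound-like images *with exact ground truth*
(boundary contour and mask), plus distance (Mean-AD/Max-AD) and overlap
(Dice/IoU/FPR) metrics, an ablation harness and a CLI.  See
[docs/methods.md](docs/methods.md) for the models, conventions and known
limitations.

## Worked example

```python
from bandseg import (PhantomSpec, PipelineConfig, default_shape_model,
                     generate_phantom, mad, overlap_metrics, segment_image)

cfg = PipelineConfig()                  # N=100 points, L=30 band, pooling 10+5
model = default_shape_model(cfg)        # built-in near-circular prior
phantom = generate_phantom(PhantomSpec(seed=12))

result = segment_image(phantom.image, model, cfg=cfg)
print(overlap_metrics(result.mask, phantom.mask))
print(mad(result.contour, phantom.contour))
```

Running `python examples/03_segment_phantom.py` (the same computation with
diagnostics) prints:

```
Dice 0.9802  IoU 0.9612  FPR 0.00112
boundary error: mean 3.49 px, std 2.23 px, max 11.95 px
runtime: 127 ms
anomalous profiles repaired: 3 (forward pass), 1 (backward pass)
largest offset correction by the denoiser: 9.6 px
```

The other scripts in `examples/` walk through shape-model fitting
(`01_shape_model.py`), phantom generation (`02_generate_phantoms.py`) and the
operator/denoiser ablation (`04_ablation.py`).  On a 10-phantom noisy suite
the ablation prints:

```
          dice    iou  mean_ad  max_ad
variant
base     0.974  0.950   19.238  43.335
nnvo     0.981  0.963    7.623  15.472
etsd     0.983  0.967    5.795  16.233
full     0.982  0.964    5.699  13.179
```

i.e. neighbourhood pooling fixes the mean error of the plain operator,
smoothing fixes the worst case, and the full pipeline has the best mean
Max-AD.

## Command line

```sh
bandseg phantom --n 5 --seed 0 --out-dir phantoms/      # synthetic data + GT
bandseg segment phantoms/phantom_000.png \
        --out-contour pred.csv --out-mask pred.png
bandseg eval --pred-mask pred.png --truth-mask phantoms/phantom_000_mask.png \
        --pred-contour pred.csv --truth-contour phantoms/phantom_000_contour.csv
bandseg train-shape contours/*.csv --out model.json     # fit a PDM
bandseg ablate --n 10 --seed 3                          # variant comparison
```

Exit codes: 0 success, 2 invalid input/config, 1 runtime error.  Pipeline
hyperparameters live in a versioned YAML config (`--config`); unknown keys
are rejected.

## Repository layout

```
src/bandseg/        library (contours, shape model, localization, narrow band,
                    operators, denoiser, metrics, phantoms, pipeline, CLI)
tests/              unit + property tests, brute-force oracles, acceptance suite
scripts/acceptance.py   seeded end-to-end results as JSON
examples/           narrative walkthroughs of each stage
docs/methods.md     models, conventions, parameter provenance, limitations
```
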