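"""Generate synthetic ultrasound-like phantoms with exact ground truth.

Each phantom is a dark, star-convex "gland" in brighter tissue with
correlated multiplicative speckle, wedge-shaped shadows crossing the
boundary, and bright patches just inside it.  The generator returns the
image together with the exact boundary contour and mask, so segmentation
error is measurable to the pixel.
"""

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from bandseg import PhantomSpec, clean_spec, generate_phantom

out_dir = Path(__file__).parent / "output"
out_dir.mkdir(exist_ok=True)

noisy = generate_phantom(PhantomSpec(seed=11))
clean = generate_phantom(clean_spec(seed=11))

for name, ph in [("noisy", noisy), ("clean", clean)]:
    inside = ph.image[ph.mask].mean()
    outside = ph.image[~ph.mask].mean()
    print(
        f"{name}: image {ph.image.shape} {ph.image.dtype}, "
        f"target area {int(ph.mask.sum())} px, "
        f"mean gray inside {inside:.1f} / outside {outside:.1f}"
    )
    iio.imwrite(out_dir / f"phantom_{name}.png", ph.image)
    iio.imwrite(out_dir / f"phantom_{name}_mask.png",
                (ph.mask * 255).astype(np.uint8))

print(f"ground-truth contour: {noisy.contour.shape[0]} points "
      "(counter-clockwise, row/col pixel coordinates)")
print(f"wrote images to {out_dir}/")
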