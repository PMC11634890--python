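"""Image reading/writing helpers for the CLI."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._errors import ValidationError

__all__ = ["read_grayscale", "write_mask_png", "write_band_png"]


def read_grayscale(path) -> np.ndarray:
    """Read a PNG/TIFF (8/16-bit) or DICOM image as a float 2-D array."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise ValidationError("DICOM input requires pydicom") from exc
        arr = pydicom.dcmread(path).pixel_array
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(float)


def write_mask_png(path, mask) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def write_band_png(path, gm, magnify: int = 1) -> None:
    """Debug export of a narrow band's transposed gray matrix as a PNG."""
    g = np.asarray(gm, dtype=float).T
    lo, hi = g.min(), g.max()
    scaled = np.zeros_like(g) if hi == lo else (g - lo) / (hi - lo) * 255.0
    img = scaled.astype(np.uint8)
    if magnify > 1:
        img = np.kron(img, np.ones((magnify, magnify), dtype=np.uint8))
    iio.imwrite(Path(path), img)
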