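"""Grayscale raster I/O with a fixed [0, 1] in-memory convention.

Supported: PNG (8/16-bit, quantized on write), TIFF (32-bit float,
lossless round-trip) and single-slice DICOM (read-only; rescale slope and
intercept applied, then min-max windowed to [0, 1]).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64 with intensities mapped to [0, 1]."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        img = Image.open(path)
        arr = np.asarray(img, dtype=np.float64)
        if arr.ndim == 3:  # collapse RGB(A) by luminance-free mean
            arr = arr[..., :3].mean(axis=-1)
        if img.mode in ("I", "I;16", "I;16B"):
            return arr / 65535.0
        return arr / 255.0
    if suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a single-plane TIFF, got shape {arr.shape}")
        return np.clip(arr, 0.0, 1.0)
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    raise ValueError(f"unsupported image format {suffix!r} (use .png, .tif/.tiff or .dcm)")


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"only single-slice DICOM is supported, got shape {arr.shape}")
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = float(arr.min()), float(arr.max())
    logger.info("DICOM %s windowed from [%g, %g] to [0, 1]", path.name, lo, hi)
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def write_image(img: np.ndarray, path: str | Path, bits: int = 16) -> None:
    """Write a [0, 1] image: float32 TIFF (lossless) or 8/16-bit PNG."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    path = Path(path)
    suffix = path.suffix.lower()
    clipped = np.clip(img, 0.0, 1.0)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, clipped.astype(np.float32))
        return
    if suffix == ".png":
        if bits == 16:
            data = np.round(clipped * 65535.0).astype(np.uint16)
            Image.fromarray(data).save(path)
        elif bits == 8:
            data = np.round(clipped * 255.0).astype(np.uint8)
            Image.fromarray(data, mode="L").save(path)
        else:
            raise ValueError(f"PNG bit depth must be 8 or 16, got {bits}")
        return
    raise ValueError(f"unsupported output format {suffix!r} (use .png or .tif/.tiff)")
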