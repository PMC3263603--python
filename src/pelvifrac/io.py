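"""Image and sidecar I/O.

All pipeline code works on floating-point images in [0, 1], indexed
0-based as (row, col).  This module converts 8/16-bit PNG/TIFF and DICOM
pixel data to that internal representation at the boundary and back.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_image", "read_json", "write_json"]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D grayscale image as float64 in [0, 1].

    PNG/TIFF integer data are divided by the dtype maximum.  DICOM pixel
    data get rescale slope/intercept applied and are then min-max
    normalized to [0, 1] (per-slice normalization; no Hounsfield
    windowing presets).
    """
    path = Path(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo)
        else:
            arr = np.zeros_like(arr)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # RGB(A) -> luminance of first channels
            arr = arr[..., :3].mean(axis=-1)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit PNG or 16-bit TIFF by suffix."""
    import imageio.v3 as iio

    path = Path(path)
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        iio.imwrite(path, (img * 65535.0 + 0.5).astype(np.uint16))
    else:
        iio.imwrite(path, (img * 255.0 + 0.5).astype(np.uint8))


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
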