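"""Slice conditioning: artifact removal, denoising, contrast, edges.

The conditioning chain prepares a raw CT-like slice for bone
segmentation: exterior artifacts (scanner table, cables) are removed by
blob analysis, high-frequency speckle noise is suppressed with a 2D
Gaussian filter, intensities are stretched to emphasize bone, and a
Canny edge map with morphological cleanup is exposed for edge-based
consumers.  All operations act on float images in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters

__all__ = [
    "PreprocessConfig",
    "remove_exterior_artifacts",
    "denoise",
    "stretch_contrast",
    "detect_edges",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain.

    gaussian_sigma : px, std of the denoising Gaussian.
    stretch_percentiles : (low, high) input percentiles mapped to [0, 1].
    canny_thresholds : (low, high) hysteresis thresholds on the gradient
        magnitude of the [0, 1] image.
    body_blob_min_fraction : blobs smaller than this fraction of the
        image area are never retained as the body.
    min_edge_length : px, edge components shorter than this are dropped.
    """

    gaussian_sigma: float = 1.0
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)
    canny_thresholds: tuple[float, float] = (0.1, 0.3)
    body_blob_min_fraction: float = 0.01
    min_edge_length: int = 10

    def validate(self) -> None:
        lo, hi = self.stretch_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("stretch percentiles must satisfy 0 <= low < high <= 100")
        cl, ch = self.canny_thresholds
        if not cl < ch:
            raise ValueError("canny low threshold must be < high threshold")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


_EIGHT = np.ones((3, 3), dtype=bool)


def remove_exterior_artifacts(image: np.ndarray, min_fraction: float = 0.01) -> np.ndarray:
    """Zero out everything outside the patient body blob.

    Blob analysis: the image is coarsely thresholded (Otsu), connected
    components are labeled with 8-connectivity, and the largest
    component — the body — is kept (holes filled, so dark interior
    structures survive).  All other pixels are set to background 0.
    If no component reaches ``min_fraction`` of the image area the image
    is returned unchanged and a warning is issued.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.max() <= image.min():
        warnings.warn("no foreground blob found; image returned unchanged")
        return image.copy()
    # CT slices are roughly trimodal (air / soft tissue / bone): the
    # lowest multi-Otsu cut separates background air from the body.
    try:
        thresh = filters.threshold_multiotsu(image, classes=3)[0]
    except ValueError:  # fewer than 3 distinct gray levels
        thresh = filters.threshold_otsu(image)
    fg = image > thresh
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        warnings.warn("no foreground blob found; image returned unchanged")
        return image.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = int(sizes.argmax())
    if sizes[largest] < min_fraction * image.size:
        warnings.warn("largest blob below min_fraction; image returned unchanged")
        return image.copy()
    body = ndimage.binary_fill_holes(labels == largest)
    out = image.copy()
    out[~body] = 0.0
    return out


def denoise(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with replicate padding (mean-preserving)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), sigma, mode="nearest")


def stretch_contrast(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Linear percentile stretch to [0, 1], clipping outside.

    The ``low_pct`` percentile maps to 0 and ``high_pct`` to 1.  A
    constant image is returned unchanged with a warning (the stretch is
    undefined).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant image; contrast stretch is a no-op")
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def detect_edges(
    image: np.ndarray,
    canny_low: float = 0.1,
    canny_high: float = 0.3,
    sigma: float = 1.0,
    min_edge_length: int = 10,
) -> np.ndarray:
    """Canny edge map with removal of short spurious edge fragments.

    Hysteresis thresholds apply to the Sobel gradient magnitude of the
    Gaussian-smoothed [0, 1] image.  Edge components (8-connected) with
    fewer than ``min_edge_length`` pixels are discarded.
    """
    edges = feature.canny(
        np.asarray(image, dtype=np.float64),
        sigma=sigma,
        low_threshold=canny_low,
        high_threshold=canny_high,
    )
    if min_edge_length > 1 and edges.any():
        labels, n = ndimage.label(edges, structure=_EIGHT)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_edge_length
        keep[0] = False
        edges = keep[labels]
    return edges


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full conditioning chain: blob analysis -> Gaussian -> stretch.

    Edge detection is exposed separately (`detect_edges`); the
    segmentation stage consumes the conditioned intensity image.
    """
    config = config or PreprocessConfig()
    config.validate()
    out = remove_exterior_artifacts(image, config.body_blob_min_fraction)
    out = denoise(out, config.gaussian_sigma)
    return stretch_contrast(out, *config.stretch_percentiles)
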