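"""Otsu thresholding and edge-window masking.

The binarized wavelet detail array W_b of a window contains the bone
contour but also redundant edges (interior texture, neighboring
structures, noise).  A mask W_m — built from the Otsu-binarized
smoothed window itself — isolates the image area occupied by bone, and
the precise edge window is their pixelwise product W_e = W_b * W_m.

Otsu's threshold maximizes the between-class variance
sigma_b^2(t) = w1 w2 (mu1 - mu2)^2 of the histogram split at t,
equivalently minimizes the within-class variance
sigma_w^2(t) = w1 sigma_1^2 + w2 sigma_2^2; their sum is the total
variance at every candidate split, which the implementation exposes so
the identity can be asserted.

Histogram binning is fixed at 256 uniform bins between the array
minimum and maximum, and binarization compares bin indices (not raw
values) against the selected cut, so results are reproducible
bit-for-bit and invariant under positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "OtsuResult",
    "otsu_threshold",
    "binarize_detail",
    "build_contour_mask",
    "apply_mask",
    "EdgeWindow",
    "N_BINS",
]

N_BINS = 256
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class OtsuResult:
    """Otsu split of a histogram: threshold and both classes' statistics.

    ``bin_index`` k means class 1 = bins 0..k, class 2 = bins k+1..;
    ``threshold`` is the corresponding intensity (lower edge of the
    first class-2 bin when bin values are supplied).
    """

    bin_index: int
    threshold: float
    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma_w2: float
    sigma_b2: float
    sigma_total2: float
    degenerate: bool = False


def otsu_threshold(histogram: np.ndarray, bin_values: np.ndarray | None = None) -> OtsuResult:
    """Exhaustive Otsu scan over all histogram cut points.

    Returns the cut maximizing the between-class variance; ties resolve
    to the smallest threshold.  A histogram with a single nonzero bin is
    degenerate (no split exists): that bin is returned with
    ``sigma_b2 = 0`` and the ``degenerate`` flag set.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("histogram must be a 1D array of counts")
    if (counts < 0).any():
        raise ValueError("histogram counts must be >= 0")
    n = counts.size
    values = np.arange(n, dtype=np.float64) if bin_values is None else np.asarray(bin_values, dtype=np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("histogram has no counts")

    p = counts / total
    mu_total = float((p * values).sum())
    var_total = float((p * (values - mu_total) ** 2).sum())

    nonzero = np.nonzero(counts)[0]
    if nonzero.size == 1:
        k = int(nonzero[0])
        return OtsuResult(
            bin_index=k,
            threshold=float(values[k]),
            w1=1.0,
            w2=0.0,
            mu1=float(values[k]),
            mu2=0.0,
            sigma_w2=0.0,
            sigma_b2=0.0,
            sigma_total2=var_total,
            degenerate=True,
        )

    w1 = np.cumsum(p)[:-1]  # cut after bin k, k = 0..n-2
    w2 = 1.0 - w1
    m1 = np.cumsum(p * values)[:-1]
    s1 = np.cumsum(p * values**2)[:-1]
    mu1 = np.divide(m1, w1, out=np.zeros_like(m1), where=w1 > 0)
    mu2 = np.divide(mu_total - m1, w2, out=np.zeros_like(m1), where=w2 > 0)
    var1 = np.divide(s1, w1, out=np.zeros_like(m1), where=w1 > 0) - mu1**2
    var2 = (
        np.divide((p * values**2).sum() - s1, w2, out=np.zeros_like(m1), where=w2 > 0)
        - mu2**2
    )
    sigma_w2 = w1 * np.maximum(var1, 0.0) + w2 * np.maximum(var2, 0.0)
    sigma_b2 = w1 * w2 * (mu1 - mu2) ** 2
    valid = (w1 > 0) & (w2 > 0)
    sigma_b2 = np.where(valid, sigma_b2, -np.inf)
    k = int(np.argmax(sigma_b2))  # argmax takes the first (smallest) maximizer
    return OtsuResult(
        bin_index=k,
        threshold=float(values[k + 1]) if k + 1 < n else float(values[k]),
        w1=float(w1[k]),
        w2=float(w2[k]),
        mu1=float(mu1[k]),
        mu2=float(mu2[k]),
        sigma_w2=float(sigma_w2[k]),
        sigma_b2=float(sigma_b2[k]),
        sigma_total2=var_total,
    )


def _bin_indices(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform 256-bin indices over [min, max] and the bin lower edges."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.int64), np.full(N_BINS, lo)
    idx = ((arr - lo) * (N_BINS / (hi - lo))).astype(np.int64)
    np.clip(idx, 0, N_BINS - 1, out=idx)
    edges = lo + np.arange(N_BINS) * (hi - lo) / N_BINS
    return idx, edges


def binarize_detail(magnitude: np.ndarray) -> np.ndarray:
    """Binary version W_b of a detail-magnitude array via Otsu.

    A flat (all-equal, e.g. all-zero) array yields an all-false W_b.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if (magnitude < 0).any():
        raise ValueError("detail magnitude must be >= 0")
    if magnitude.max() <= magnitude.min():
        return np.zeros(magnitude.shape, dtype=bool)
    idx, edges = _bin_indices(magnitude)
    res = otsu_threshold(np.bincount(idx.ravel(), minlength=N_BINS), bin_values=edges)
    return idx > res.bin_index


@dataclass
class EdgeWindow:
    w_b: np.ndarray  # binarized detail
    w_m: np.ndarray  # bone-area mask
    w_e: np.ndarray  # product (pixelwise AND)


def build_contour_mask(
    scaled_window: np.ndarray,
    sigma_mask: float = 2.0,
    dilation_radius: int = 5,
    min_component_fraction: float = 0.005,
    border_margin: int = 16,
) -> np.ndarray:
    """Mask W_m of the image area occupied by bone in a scaled window.

    The window is Gaussian-smoothed, Otsu-binarized, foreground
    components above ``min_component_fraction`` of the window area are
    kept (every bone piece in view, so fracture fragments on both sides
    of a gap stay inside the mask), holes are filled, and the mask
    becomes the band within ``dilation_radius`` of each piece's
    contour.  An empty foreground yields an all-false mask (and
    downstream an empty-window verdict).

    ``border_margin`` pixels at the window border are excluded from the
    mask: where the bone is clipped by the window frame its apparent
    contour follows the frame, not the bone, and the periodic wavelet
    analysis responds to the wrap-around intensity jump exactly there.
    """
    win = np.asarray(scaled_window, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(win, sigma_mask, mode="nearest")
    if smoothed.max() <= smoothed.min():
        return np.zeros(win.shape, dtype=bool)
    idx, edges = _bin_indices(smoothed)
    res = otsu_threshold(np.bincount(idx.ravel(), minlength=N_BINS), bin_values=edges)
    fg = idx > res.bin_index
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        return np.zeros(win.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_fraction * win.size
    keep[0] = False
    mask = keep[labels]
    if not mask.any():
        return mask
    mask = ndimage.binary_fill_holes(mask)
    if dilation_radius > 0:
        yy, xx = np.mgrid[-dilation_radius : dilation_radius + 1, -dilation_radius : dilation_radius + 1]
        disk = yy**2 + xx**2 <= dilation_radius**2
        # Band of +/- dilation_radius around each piece's contour: wide
        # enough to hold the wavelet edge ridge (and dual edges of minor
        # fractures), narrow enough to exclude the transform's interior
        # side lobes, which would otherwise count as extra boundaries.
        outer = ndimage.binary_dilation(mask, structure=disk)
        inner = ndimage.binary_erosion(mask, structure=disk)
        mask = outer & ~inner
    if border_margin > 0:
        b = border_margin
        mask[:b, :] = False
        mask[-b:, :] = False
        mask[:, :b] = False
        mask[:, -b:] = False
    return mask


def apply_mask(w_b: np.ndarray, w_m: np.ndarray) -> np.ndarray:
    """Precise edge window W_e = W_b x W_m (pixelwise AND)."""
    w_b = np.asarray(w_b)
    w_m = np.asarray(w_m)
    if w_b.shape != w_m.shape:
        raise ValueError(f"shape mismatch: {w_b.shape} vs {w_m.shape}")
    return w_b.astype(bool) & w_m.astype(bool)


def edge_window(
    magnitude: np.ndarray,
    scaled_window: np.ndarray,
    sigma_mask: float = 2.0,
    dilation_radius: int = 5,
    min_component_fraction: float = 0.005,
    border_margin: int = 16,
    detail_sigma: float = 2.0,
) -> EdgeWindow:
    """Full masking stage for one window: W_b, W_m and W_e = W_b x W_m.

    Two robustness steps precede the core Otsu binarization:

    * The detail magnitude is smoothed into its envelope
      (``detail_sigma``) before thresholding — ridge strength
      oscillates along oblique edges, which would speckle W_b.
    * The border frame of M is zeroed (``border_margin``): with
      periodic analysis the wrap-around jump at the window frame
      produces the strongest, purely artificial ridges, which would
      otherwise dominate the Otsu split and drown the bone edges.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if detail_sigma > 0:
        magnitude = ndimage.gaussian_filter(magnitude, detail_sigma, mode="nearest")
    if border_margin > 0:
        b = border_margin
        magnitude = magnitude.copy()
        magnitude[:b, :] = 0.0
        magnitude[-b:, :] = 0.0
        magnitude[:, :b] = 0.0
        magnitude[:, -b:] = 0.0
    w_b = binarize_detail(magnitude)
    w_m = build_contour_mask(
        scaled_window,
        sigma_mask=sigma_mask,
        dilation_radius=dilation_radius,
        min_component_fraction=min_component_fraction,
        border_margin=border_margin,
    )
    return EdgeWindow(w_b=w_b, w_m=w_m, w_e=apply_mask(w_b, w_m))


def dump_triptych(ew: EdgeWindow, path) -> None:
    """Debug dump: W_b | W_m | W_e side by side as one PNG."""
    from . import io as pfio

    trip = np.concatenate(
        [ew.w_b.astype(float), ew.w_m.astype(float), ew.w_e.astype(float)], axis=1
    )
    pfio.write_image(path, trip)


def bridge_breaks(w_e: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Binary closing that bridges residual sub-ridge breaks in W_e.

    The closing disk is far smaller than any fracture gap at window
    scale, so genuine discontinuities survive while hairline breaks in
    an otherwise continuous traced edge are healed.
    """
    w_e = np.asarray(w_e, dtype=bool)
    if closing_radius <= 0 or not w_e.any():
        return w_e.copy()
    yy, xx = np.mgrid[-closing_radius : closing_radius + 1, -closing_radius : closing_radius + 1]
    disk = yy**2 + xx**2 <= closing_radius**2
    return ndimage.binary_closing(w_e, structure=disk)
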