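"""Adaptive, landmark-centered square windows.

Local edge analysis must adapt to bone size: each window is a square
subimage centered on a boundary landmark whose area is the bone area
divided by the empirical constant 6, so the window is small relative to
the bone and its stretch of boundary is locally simple.  Each raw
window is rescaled to 256x256 by bilinear interpolation before wavelet
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .segmentation import BoneRegion

__all__ = [
    "WindowGeometry",
    "AdaptiveWindow",
    "window_geometry",
    "extract_and_scale",
    "windows_for_bone",
    "SCALED_SIZE",
]

SCALED_SIZE = 256
AREA_DIVISOR = 6.0  # empirical window-area constant: W = A / 6


@dataclass(frozen=True)
class WindowGeometry:
    center: tuple[int, int]  # landmark (row, col)
    window_area: float  # W = A / 6, px^2
    side: int  # odd side length S, px
    bone_index: int = 0
    landmark_index: int = 0
    clamped: bool = False  # True when the bone was too small and S hit 3


@dataclass
class AdaptiveWindow:
    geometry: WindowGeometry
    raw: np.ndarray  # (S, S) crop centered on the landmark
    scaled: np.ndarray  # (256, 256) bilinear rescale of raw


def _nearest_odd(x: float) -> int:
    """Nearest odd integer; exact ties resolve to the smaller candidate."""
    lo = int(math.floor(x))
    lo = lo if lo % 2 == 1 else lo - 1
    hi = lo + 2
    return lo if (x - lo) <= (hi - x) else hi


def window_geometry(
    area: float,
    landmark: tuple[int, int],
    bone_index: int = 0,
    landmark_index: int = 0,
) -> WindowGeometry:
    """Window area ``W = A/6`` and odd side ``S = nearest_odd(sqrt(A/6))``.

    The side is forced odd so the landmark occupies an exact center
    pixel, and clamped to a minimum of 3 (flagged when the bone area is
    degenerate, i.e. ``sqrt(A/6) < 3``).
    """
    if area <= 0:
        raise ValueError("bone area must be > 0")
    w = area / AREA_DIVISOR
    s_real = math.sqrt(w)
    side = _nearest_odd(s_real)
    clamped = s_real < 3.0
    side = max(side, 3)
    return WindowGeometry(
        center=(int(landmark[0]), int(landmark[1])),
        window_area=w,
        side=side,
        bone_index=bone_index,
        landmark_index=landmark_index,
        clamped=clamped,
    )


def extract_and_scale(image: np.ndarray, geometry: WindowGeometry) -> AdaptiveWindow:
    """Crop the S x S window centered on the landmark and rescale to 256x256.

    The crop is replicate-padded where it exceeds the image bounds (no
    fake zero-intensity borders).  Rescaling is bilinear with no
    renormalization, so the intensity range is preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    r, c = geometry.center
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"landmark {geometry.center} outside image of shape {image.shape}")
    half = geometry.side // 2
    r0, r1 = r - half, r + half + 1
    c0, c1 = c - half, c + half + 1
    pad_top, pad_bottom = max(0, -r0), max(0, r1 - h)
    pad_left, pad_right = max(0, -c0), max(0, c1 - w)
    crop = image[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)]
    if pad_top or pad_bottom or pad_left or pad_right:
        crop = np.pad(crop, ((pad_top, pad_bottom), (pad_left, pad_right)), mode="edge")
    scaled = resize(
        crop,
        (SCALED_SIZE, SCALED_SIZE),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return AdaptiveWindow(geometry=geometry, raw=crop, scaled=scaled)


def windows_for_bone(image: np.ndarray, region: BoneRegion) -> list[AdaptiveWindow]:
    """One window per landmark of the region, in landmark order."""
    if region.landmarks is None:
        raise ValueError("region has no landmarks; call place_landmarks first")
    out = []
    for k, lm in enumerate(region.landmarks):
        geom = window_geometry(
            region.area, (int(lm[0]), int(lm[1])), bone_index=region.bone_index, landmark_index=k
        )
        out.append(extract_and_scale(image, geom))
    return out


def dump_windows(windows: list[AdaptiveWindow], outdir) -> None:
    """Debug dump: each scaled window as ``bone{p}_lm{k}.png``."""
    from pathlib import Path

    from . import io as pfio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for w in windows:
        g = w.geometry
        pfio.write_image(outdir / f"bone{g.bone_index}_lm{g.landmark_index}.png", w.scaled)
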