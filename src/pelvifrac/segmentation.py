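"""Simplified bone segmentation: masks, boundaries, landmarks.

Produces the inputs the windowing stage needs — a binary mask, its
pixel area, an ordered closed outer-boundary path, and equally spaced
boundary landmarks — for each bright bone-like region of a conditioned
slice.  This is an intensity-threshold stand-in for a full statistical
shape-model segmenter; externally produced masks and landmark sidecars
can be plugged in unchanged through ``regions_from_json``.

Conventions (fixed for reproducibility): 8-connectivity throughout;
boundary paths are closed, counter-clockwise in display coordinates
(x = col rightwards, y = row downwards), and start at the topmost-then-
leftmost boundary pixel; landmarks are boundary pixels sampled at equal
arc-length intervals starting from that pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BoneRegion",
    "extract_bone_regions",
    "place_landmarks",
    "trace_outer_boundary",
    "regions_to_json",
    "regions_from_json",
]

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighborhood offsets in clockwise order (image coordinates,
# row down): W, NW, N, NE, E, SE, S, SW.
_MOORE_CW = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass
class BoneRegion:
    """One segmented bone: mask, area, ordered boundary, landmarks."""

    mask: np.ndarray  # binary, holes filled
    area: int  # pixel count of mask
    boundary: np.ndarray  # (m, 2) ordered closed path of (row, col)
    bone_index: int
    landmarks: np.ndarray | None = field(default=None)  # (l, 2) of (row, col)


def _start_pixel(mask: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(mask)
    k = np.lexsort((cols, rows))[0]
    return int(rows[k]), int(cols[k])


def trace_outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer boundary of a connected binary region.

    Moore-neighbor tracing with Jacob's stopping criterion, then the
    path is oriented counter-clockwise (display coordinates) keeping
    the topmost-leftmost start pixel first.  Consecutive path pixels
    are 8-adjacent; the last pixel is 8-adjacent to the first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    h, w = mask.shape

    def fg(p):
        r, c = p
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    start = _start_pixel(mask)
    if int(mask.sum()) == 1:
        return np.array([start], dtype=np.int64)
    # Backtrack pixel starts west of start, guaranteed background for a
    # topmost-then-leftmost start pixel.
    b = (start[0], start[1] - 1)
    c = start
    path = [start]
    first_state: tuple | None = None
    for _ in range(4 * int(mask.sum()) + 16):
        db = (b[0] - c[0], b[1] - c[1])
        i0 = _MOORE_CW.index(db)
        for step in range(1, 9):
            d = (i0 + step) % 8
            cand = (c[0] + _MOORE_CW[d][0], c[1] + _MOORE_CW[d][1])
            if fg(cand):
                prev = (d - 1) % 8
                b = (c[0] + _MOORE_CW[prev][0], c[1] + _MOORE_CW[prev][1])
                c = cand
                break
        else:  # isolated pixel (cannot happen for mask.sum() > 1 connected)
            break
        state = (c, b)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break  # Jacob's criterion: same pixel entered the same way
        path.append(c)
    if len(path) > 1 and path[-1] == path[0]:
        path.pop()
    arr = np.array(path, dtype=np.int64)
    if len(arr) >= 3:
        x = arr[:, 1].astype(np.float64)
        y = arr[:, 0].astype(np.float64)
        # Shoelace in display coords (y down): positive area = clockwise.
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area2 > 0:
            arr = np.vstack([arr[:1], arr[1:][::-1]])
    return arr


def _path_arclengths(boundary: np.ndarray) -> tuple[np.ndarray, float]:
    """Cumulative arc length at each path vertex and the closed total."""
    diffs = np.diff(boundary, axis=0)
    seg = np.hypot(diffs[:, 0], diffs[:, 1])
    closing = float(np.hypot(*(boundary[0] - boundary[-1])))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum, float(cum[-1] + closing)


def place_landmarks(region: BoneRegion, l: int = 50) -> BoneRegion:
    """Sample ``l`` landmarks along the boundary at equal arc length.

    Landmark 0 is the boundary start pixel (topmost-then-leftmost);
    subsequent landmarks sit at the boundary vertex nearest to each
    multiple of (total length / l).  Deterministic; raises if ``l``
    exceeds the number of boundary pixels.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    boundary = region.boundary
    if l > len(boundary):
        raise ValueError(f"l={l} exceeds boundary length {len(boundary)}")
    cum, total = _path_arclengths(boundary)
    targets = np.arange(l) * total / l
    idx = np.searchsorted(cum, targets)
    idx = np.clip(idx, 0, len(boundary) - 1)
    # snap to the nearer of the bracketing vertices
    prev = np.clip(idx - 1, 0, len(boundary) - 1)
    use_prev = np.abs(cum[prev] - targets) < np.abs(cum[idx] - targets)
    idx = np.where(use_prev, prev, idx)
    region.landmarks = boundary[idx].copy()
    return region


def extract_bone_regions(
    image: np.ndarray,
    bone_threshold: float = 0.6,
    min_bone_area: int = 300,
    n_landmarks: int | None = None,
    close_radius: int = 12,
) -> list[BoneRegion]:
    """Segment bright bone-like regions of a conditioned slice.

    The thresholded mask (``image >= bone_threshold``) is closed with a
    disk of ``close_radius`` before labeling (8-connectivity), then each
    component is hole-filled; components with filled area >=
    ``min_bone_area`` become regions, ordered by decreasing area.  If
    ``n_landmarks`` is given, landmarks are placed on each region.

    The closing makes the region describe the bone as a whole: a
    fracture gap narrower than twice the radius does not split the bone
    into separate regions, so — like a shape-model segmenter fitting
    the overall bone — the traced outline passes across the gap, the
    area reflects the whole bone, and the windows centered there are
    sized to contain both fragments.  Distinct bones must be farther
    apart than twice the radius to remain separate.
    """
    image = np.asarray(image, dtype=np.float64)
    fg = image >= bone_threshold
    if close_radius > 0 and fg.any():
        yy, xx = np.mgrid[-close_radius : close_radius + 1, -close_radius : close_radius + 1]
        disk = yy**2 + xx**2 <= close_radius**2
        fg = ndimage.binary_closing(fg, structure=disk)
    labels, n = ndimage.label(fg, structure=_EIGHT)
    regions: list[BoneRegion] = []
    for lab in range(1, n + 1):
        filled = ndimage.binary_fill_holes(labels == lab)
        area = int(filled.sum())
        if area < min_bone_area:
            continue
        boundary = trace_outer_boundary(filled)
        regions.append(BoneRegion(mask=filled, area=area, boundary=boundary, bone_index=0))
    regions.sort(key=lambda r: -r.area)
    for i, region in enumerate(regions):
        region.bone_index = i
        if n_landmarks is not None:
            place_landmarks(region, n_landmarks)
    return regions


def regions_to_json(regions: list[BoneRegion]) -> dict:
    """Landmark sidecar: {bones: [{index, area, landmarks: [[row, col], ...]}]}."""
    return {
        "bones": [
            {
                "index": r.bone_index,
                "area": r.area,
                "landmarks": None
                if r.landmarks is None
                else [[int(a), int(b)] for a, b in r.landmarks],
            }
            for r in regions
        ]
    }


def regions_from_json(sidecar: dict, masks: list[np.ndarray]) -> list[BoneRegion]:
    """Rebuild regions from a landmark sidecar plus externally supplied masks."""
    regions = []
    for entry, mask in zip(sidecar["bones"], masks):
        mask = np.asarray(mask, dtype=bool)
        boundary = trace_outer_boundary(mask)
        landmarks = entry.get("landmarks")
        regions.append(
            BoneRegion(
                mask=mask,
                area=int(entry.get("area", int(mask.sum()))),
                boundary=boundary,
                bone_index=int(entry["index"]),
                landmarks=None if landmarks is None else np.asarray(landmarks, dtype=np.int64),
            )
        )
    return regions
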