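"""Overlay rendering of detection results on the source slice."""

from __future__ import annotations

import numpy as np

from .pipeline import SliceReport
from .windows import SCALED_SIZE, window_geometry

__all__ = ["draw_overlay"]

_GREEN = (0.1, 0.9, 0.1)
_RED = (1.0, 0.15, 0.15)
_YELLOW = (1.0, 0.85, 0.1)


def draw_overlay(image: np.ndarray, report: SliceReport) -> np.ndarray:
    """RGB overlay: segmentation boundaries green, traced boundaries of
    fractured windows red, fractured-window outlines yellow."""
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    rgb = np.stack([img, img, img], axis=-1)
    h, w = img.shape

    def paint(rr, cc, color):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[ok], cc[ok]] = color

    for bone in report.bones:
        if bone.region is not None:
            b = bone.region.boundary
            paint(b[:, 0], b[:, 1], _GREEN)
        for verdict in bone.verdicts:
            if not verdict.fractured:
                continue
            if bone.region is None or bone.region.landmarks is None:
                continue
            lm = bone.region.landmarks[verdict.landmark_index]
            # recover the raw window frame to place traced pixels
            geom = window_geometry(bone.area, (int(lm[0]), int(lm[1])))
            half = geom.side // 2
            r0, c0 = int(lm[0]) - half, int(lm[1]) - half
            scale = geom.side / SCALED_SIZE
            for tb in verdict.boundaries:
                pos = tb.positions
                rr = (r0 + ((pos[:, 0] + 0.5) * scale - 0.5)).round().astype(int)
                cc = (c0 + ((pos[:, 1] + 0.5) * scale - 0.5)).round().astype(int)
                paint(rr, cc, _RED)
            # window outline
            rr = np.arange(r0, r0 + geom.side)
            cc = np.arange(c0, c0 + geom.side)
            paint(rr, np.full_like(rr, c0), _YELLOW)
            paint(rr, np.full_like(rr, c0 + geom.side - 1), _YELLOW)
            paint(np.full_like(cc, r0), cc, _YELLOW)
            paint(np.full_like(cc, r0 + geom.side - 1), cc, _YELLOW)
    return rgb
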