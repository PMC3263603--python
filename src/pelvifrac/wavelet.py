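"""Stationary (undecimated) 2D Haar wavelet analysis of scaled windows.

The stationary wavelet transform (SWT, a-trous algorithm) decomposes an
image without decimation: coefficient arrays keep full size at every
level, the filters at level j are the level-(j-1) filters upsampled by
zero insertion, and — with periodic boundary handling, used here — the
transform is exactly equivariant under circular shifts.  Haar analysis
filters are the two-tap pair lo = [1, 1]/sqrt(2), hi = [-1, 1]/sqrt(2),
applied as circular correlation y[n] = sum_k f[k] x[(n + k) mod N].

Orientation convention: the *horizontal* detail cD^(h) responds to
intensity steps across columns (vertical edges), the *vertical* detail
cD^(v) to steps across rows, and cD^(d) to diagonal structure.

Analysis is delegated to PyWavelets' ``swt2`` (remapped to the above
convention); detail/approximation reconstruction uses a closed-form
Haar a-trous synthesis (two-tap averaging per axis and level), which is
exact and is cross-checked against ``pywt.iswt2`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "SwtCoefficients",
    "DetailArrays",
    "swt2_haar",
    "reconstruct_details",
    "reconstruct_approx",
    "detail_magnitude",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class SwtLevel:
    """Coefficients of one decomposition level (all arrays input-sized)."""

    approx: np.ndarray
    horiz: np.ndarray  # cD^(h): steps across columns
    vert: np.ndarray  # cD^(v): steps across rows
    diag: np.ndarray  # cD^(d)


@dataclass
class SwtCoefficients:
    levels: dict[int, SwtLevel]  # keyed by level 1..n (n = coarsest)
    n_levels: int
    shape: tuple[int, int]

    def level(self, j: int) -> SwtLevel:
        if j not in self.levels:
            raise ValueError(f"level {j} not decomposed (have 1..{self.n_levels})")
        return self.levels[j]


@dataclass
class DetailArrays:
    """Detail images reconstructed from one level's coefficients."""

    d_h: np.ndarray
    d_v: np.ndarray
    d_d: np.ndarray
    level: int

    @property
    def magnitude(self) -> np.ndarray:
        """Combined edge response M = |D_h| + |D_v| + |D_d| (>= 0)."""
        return np.abs(self.d_h) + np.abs(self.d_v) + np.abs(self.d_d)


def swt2_haar(window: np.ndarray, levels: int = 3) -> SwtCoefficients:
    """Level-``levels`` undecimated 2D Haar decomposition.

    Both image dimensions must be divisible by ``2**levels``; otherwise
    a ``ValueError`` states the padding that would be required.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2:
        raise ValueError("window must be 2D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    div = 2**levels
    if window.shape[0] % div or window.shape[1] % div:
        need = tuple(((-s) % div) for s in window.shape)
        raise ValueError(
            f"shape {window.shape} not divisible by 2^{levels}={div}; "
            f"pad by {need} (rows, cols) first"
        )
    res = pywt.swt2(window, "haar", level=levels)  # coarsest-first
    out: dict[int, SwtLevel] = {}
    for j in range(1, levels + 1):
        cA, (cH, cV, cD) = res[levels - j]
        # pywt's cH/cV are swapped and negated relative to our plain
        # correlation convention: remap so cD^(h) = lo(rows) x hi(cols).
        out[j] = SwtLevel(approx=cA, horiz=-cV, vert=-cH, diag=cD)
    return SwtCoefficients(levels=out, n_levels=levels, shape=window.shape)


def _synth_approx(a: np.ndarray, step: int, axis: int) -> np.ndarray:
    """Approximation branch of the 1D Haar a-trous inverse."""
    return (a + np.roll(a, step, axis=axis)) / (2.0 * _SQRT2)


def _synth_detail(d: np.ndarray, step: int, axis: int) -> np.ndarray:
    """Detail branch of the 1D Haar a-trous inverse."""
    return (-d + np.roll(d, step, axis=axis)) / (2.0 * _SQRT2)


def _propagate_down(x: np.ndarray, from_level: int) -> np.ndarray:
    """Carry a level-``from_level`` approximation contribution to level 0."""
    for j in range(from_level - 1, 0, -1):
        step = 2 ** (j - 1)
        x = _synth_approx(x, step, axis=0)
        x = _synth_approx(x, step, axis=1)
    return x


def reconstruct_details(coeffs: SwtCoefficients, level: int = 3) -> DetailArrays:
    """Reconstruct the detail images D_h, D_v, D_d of one level.

    The inverse transform is applied with the approximation and every
    other level's details zeroed, once per orientation.
    """
    lev = coeffs.level(level)
    step = 2 ** (level - 1)
    # orientation -> (axis-0 branch, axis-1 branch)
    d_h = _synth_approx(_synth_detail(lev.horiz, step, axis=1), step, axis=0)
    # For the vertical detail the hi filter acts along rows (axis 0):
    d_v = _synth_approx(_synth_detail(lev.vert, step, axis=0), step, axis=1)
    d_d = _synth_detail(_synth_detail(lev.diag, step, axis=0), step, axis=1)
    return DetailArrays(
        d_h=_propagate_down(d_h, level),
        d_v=_propagate_down(d_v, level),
        d_d=_propagate_down(d_d, level),
        level=level,
    )


def reconstruct_approx(coeffs: SwtCoefficients) -> np.ndarray:
    """Reconstruct the approximation-only image from the coarsest level."""
    n = coeffs.n_levels
    a = coeffs.level(n).approx
    step = 2 ** (n - 1)
    a = _synth_approx(a, step, axis=0)
    a = _synth_approx(a, step, axis=1)
    return _propagate_down(a, n)


def coefficient_magnitude(coeffs: SwtCoefficients, level: int = 3) -> np.ndarray:
    """Combined magnitude |cD^(h)| + |cD^(v)| + |cD^(d)| of one level's
    analysis coefficients.

    Unlike the reconstructed detail arrays — which are band-pass and
    therefore odd around an edge, with an exact zero on the edge line —
    the analysis coefficients of a (blurred) step are single-signed and
    peak at the edge, so their magnitude forms an unbroken ridge along
    it.  This makes the coefficient magnitude the more robust edge map
    for binarization.
    """
    lev = coeffs.level(level)
    return np.abs(lev.horiz) + np.abs(lev.vert) + np.abs(lev.diag)


def detail_magnitude(
    window: np.ndarray,
    levels: int = 3,
    level: int | None = None,
    source: str = "reconstructed",
) -> np.ndarray:
    """Combined level-``level`` detail magnitude of a window.

    ``source`` selects the reconstructed detail arrays
    (|D_h| + |D_v| + |D_d|) or the analysis coefficients
    (|cD^(h)| + |cD^(v)| + |cD^(d)|).
    """
    coeffs = swt2_haar(window, levels=levels)
    if source == "coefficients":
        return coefficient_magnitude(coeffs, level=level or levels)
    if source == "reconstructed":
        return reconstruct_details(coeffs, level=level or levels).magnitude
    raise ValueError(f"unknown detail source {source!r}")
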