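"""Stationary Haar transform: conventions, exactness, reconstruction."""

import numpy as np
import pytest
import pywt

from pelvifrac.wavelet import (
    coefficient_magnitude,
    detail_magnitude,
    reconstruct_approx,
    reconstruct_details,
    swt2_haar,
)

LO = np.array([1.0, 1.0]) / np.sqrt(2.0)
HI = np.array([-1.0, 1.0]) / np.sqrt(2.0)


def circular_correlate(arr, filt, axis):
    """Oracle: y[n] = sum_k f[k] * x[(n + k) mod N] along one axis."""
    out = np.zeros_like(arr, dtype=float)
    for k, fk in enumerate(filt):
        out += fk * np.roll(arr, -k, axis=axis)
    return out


def level1_oracle(image):
    """Direct separable circular correlation with the Haar pair."""
    return {
        "approx": circular_correlate(circular_correlate(image, LO, 0), LO, 1),
        "horiz": circular_correlate(circular_correlate(image, LO, 0), HI, 1),
        "vert": circular_correlate(circular_correlate(image, HI, 0), LO, 1),
        "diag": circular_correlate(circular_correlate(image, HI, 0), HI, 1),
    }


class TestSwt2Haar:
    def test_constant_input_zero_details(self):
        c = swt2_haar(np.full((32, 32), 2.5), levels=3)
        for j in (1, 2, 3):
            lev = c.level(j)
            assert np.abs(lev.horiz).max() == 0.0
            assert np.abs(lev.vert).max() == 0.0
            assert np.abs(lev.diag).max() == 0.0

    def test_vertical_step_excites_horizontal_detail_only(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        lev = swt2_haar(img, levels=1).level(1)
        cols = set(np.nonzero(lev.horiz)[1])
        assert cols == {7, 15}  # adjacent to the step and the periodic wrap
        assert np.abs(lev.vert).max() == 0.0

    def test_level1_matches_convolution_oracle(self, rng):
        for _ in range(10):
            img = rng.normal(size=(32, 32))
            lev = swt2_haar(img, levels=1).level(1)
            oracle = level1_oracle(img)
            np.testing.assert_allclose(lev.approx, oracle["approx"], atol=1e-12)
            np.testing.assert_allclose(lev.horiz, oracle["horiz"], atol=1e-12)
            np.testing.assert_allclose(lev.vert, oracle["vert"], atol=1e-12)
            np.testing.assert_allclose(lev.diag, oracle["diag"], atol=1e-12)

    def test_circular_shift_equivariance(self, rng):
        img = rng.normal(size=(64, 64))
        a = swt2_haar(img, levels=3)
        b = swt2_haar(np.roll(img, (8, 8), axis=(0, 1)), levels=3)
        for j in (1, 2, 3):
            for name in ("approx", "horiz", "vert", "diag"):
                np.testing.assert_array_equal(
                    np.roll(getattr(a.level(j), name), (8, 8), axis=(0, 1)),
                    getattr(b.level(j), name),
                )

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 32, 32))
        cx = swt2_haar(x, 2)
        cy = swt2_haar(y, 2)
        cz = swt2_haar(2.0 * x - 0.5 * y, 2)
        for j in (1, 2):
            np.testing.assert_allclose(
                cz.level(j).diag, 2.0 * cx.level(j).diag - 0.5 * cy.level(j).diag, atol=1e-10
            )

    def test_noise_detail_energy_grows_with_sigma(self, rng):
        energies = []
        for sigma in (0.01, 0.05, 0.2):
            img = rng.normal(0, sigma, size=(64, 64))
            lev = swt2_haar(img, levels=3).level(3)
            energies.append((lev.horiz**2 + lev.vert**2 + lev.diag**2).sum())
        assert energies[0] < energies[1] < energies[2]

    def test_indivisible_shape_rejected_with_padding_hint(self):
        with pytest.raises(ValueError, match="pad"):
            swt2_haar(np.zeros((36, 36)), levels=3)

    def test_bad_level_request_rejected(self, rng):
        c = swt2_haar(rng.normal(size=(16, 16)), levels=2)
        with pytest.raises(ValueError, match="level"):
            c.level(3)


class TestReconstruction:
    def test_zero_coefficients_give_zero_details(self):
        c = swt2_haar(np.zeros((32, 32)), levels=3)
        d = reconstruct_details(c, 3)
        assert np.abs(d.magnitude).max() == 0.0

    def test_perfect_reconstruction_additivity(self, rng):
        img = rng.normal(size=(64, 64))
        c = swt2_haar(img, levels=3)
        total = reconstruct_approx(c)
        for j in (1, 2, 3):
            d = reconstruct_details(c, j)
            total = total + d.d_h + d.d_v + d.d_d
        np.testing.assert_allclose(total, img, rtol=0, atol=1e-6 * np.abs(img).max())

    def test_matches_pywt_iswt2_selective(self, rng):
        img = rng.normal(size=(32, 32))
        c = swt2_haar(img, levels=3)
        ref = pywt.swt2(img, "haar", level=3)
        zero = np.zeros_like(img)
        for j, pywt_name in ((1, "v"), (2, "v"), (3, "v")):
            mine = reconstruct_details(c, j).d_h  # our horiz == pywt cV slot
            sel = []
            for i, (cA, (cH, cV, cD)) in enumerate(ref):
                keep = i == 3 - j
                sel.append((zero, (zero, cV if keep else zero, zero)))
            np.testing.assert_allclose(mine, pywt.iswt2(sel, "haar"), atol=1e-12)

    def test_step_edge_magnitude_peaks_near_edge(self):
        img = np.zeros((64, 64))
        img[:, 40:] = 1.0
        c = swt2_haar(img, levels=3)
        for level in (1, 2, 3):
            m = reconstruct_details(c, level).magnitude
            # interior only: the periodic wrap at the frame is also a step
            col = 16 + int(np.argmax(m[32][16:56]))
            assert abs(col - 39.5) <= 2**level

    def test_magnitude_nonnegative_and_zero_iff_details_zero(self, rng):
        c = swt2_haar(rng.normal(size=(32, 32)), levels=2)
        d = reconstruct_details(c, 2)
        assert (d.magnitude >= 0).all()
        zero = d.magnitude == 0
        np.testing.assert_array_equal(
            zero, (d.d_h == 0) & (d.d_v == 0) & (d.d_d == 0)
        )


class TestDetailMagnitude:
    def test_sources_agree_on_support_scale(self, rng):
        img = rng.normal(size=(32, 32))
        rec = detail_magnitude(img, levels=2, source="reconstructed")
        coef = detail_magnitude(img, levels=2, source="coefficients")
        assert rec.shape == coef.shape == (32, 32)
        assert (coef >= 0).all()

    def test_coefficient_magnitude_has_no_edge_valley(self):
        # a blurred step: reconstructed |D| dips to ~0 on the edge line,
        # the analysis-coefficient magnitude stays high there
        x = np.linspace(-8, 8, 64)
        img = np.tile(1 / (1 + np.exp(-x)), (64, 1))
        c = swt2_haar(img, levels=3)
        # interior only: the periodic wrap at the frame is also a step
        rec = reconstruct_details(c, 3).magnitude[32][16:48]
        coef = coefficient_magnitude(c, 3)[32][16:48]
        mid = 31 - 16  # edge centerline column (between 31 and 32)
        assert rec[mid] < 0.2 * rec.max()
        assert coef[mid] > 0.8 * coef.max()

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            detail_magnitude(np.zeros((16, 16)), levels=1, source="bogus")
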