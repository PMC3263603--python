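"""Otsu thresholding and the W_e = W_b x W_m combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from skimage import filters

from pelvifrac.masking import (
    N_BINS,
    apply_mask,
    binarize_detail,
    build_contour_mask,
    edge_window,
    otsu_threshold,
)


def brute_force_otsu(counts, values=None):
    """Oracle: direct evaluation of both class variances at every cut."""
    counts = np.asarray(counts, dtype=float)
    values = np.arange(counts.size, dtype=float) if values is None else np.asarray(values, float)
    total = counts.sum()
    best_k, best_sb = None, -np.inf
    rows = []
    for k in range(counts.size - 1):
        c1, c2 = counts[: k + 1], counts[k + 1 :]
        v1, v2 = values[: k + 1], values[k + 1 :]
        w1, w2 = c1.sum() / total, c2.sum() / total
        if w1 == 0 or w2 == 0:
            rows.append(None)
            continue
        mu1 = (c1 * v1).sum() / c1.sum()
        mu2 = (c2 * v2).sum() / c2.sum()
        var1 = (c1 * (v1 - mu1) ** 2).sum() / c1.sum()
        var2 = (c2 * (v2 - mu2) ** 2).sum() / c2.sum()
        sw = w1 * var1 + w2 * var2
        sb = w1 * w2 * (mu1 - mu2) ** 2
        rows.append((sw, sb))
        if sb > best_sb:
            best_sb, best_k = sb, k
    return best_k, rows


class TestOtsuThreshold:
    def test_symmetric_bimodal(self):
        counts = np.zeros(256)
        counts[0] = 50
        counts[255] = 50
        res = otsu_threshold(counts)
        assert res.w1 == pytest.approx(0.5) and res.w2 == pytest.approx(0.5)
        assert res.sigma_b2 == pytest.approx(127.5**2)
        assert res.mu1 == 0.0 and res.mu2 == 255.0

    def test_single_bin_degenerate(self):
        counts = np.zeros(256)
        counts[17] = 99
        res = otsu_threshold(counts)
        assert res.degenerate and res.bin_index == 17 and res.sigma_b2 == 0.0

    def test_matches_bruteforce_on_random_histograms(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 100, size=256)
            if np.count_nonzero(counts) < 2:
                continue
            res = otsu_threshold(counts)
            k_oracle, _ = brute_force_otsu(counts)
            assert res.bin_index == k_oracle

    def test_variance_identity_at_selected_cut(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=64)
            if np.count_nonzero(counts) < 2:
                continue
            res = otsu_threshold(counts)
            assert res.sigma_w2 + res.sigma_b2 == pytest.approx(
                res.sigma_total2, rel=1e-9, abs=1e-12
            )

    def test_agrees_with_skimage(self, rng):
        img = np.concatenate([rng.normal(0.2, 0.05, 3000), rng.normal(0.8, 0.05, 2000)])
        img = np.clip(img, 0, 1)
        counts, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        res = otsu_threshold(counts, bin_values=centers)
        ref = filters.threshold_otsu(img, nbins=256)
        assert abs(res.threshold - ref) < (edges[1] - edges[0]) * 2

    def test_scale_invariant_counts(self, rng):
        counts = rng.integers(0, 40, size=128)
        counts[3] += 1  # ensure >= 2 nonzero bins
        counts[90] += 1
        assert otsu_threshold(counts).bin_index == otsu_threshold(counts * 7).bin_index

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(16))


class TestBinarizeDetail:
    def test_zero_magnitude_empty(self):
        assert not binarize_detail(np.zeros((32, 32))).any()

    def test_bright_ridge_separated_from_background(self, rng):
        m = np.abs(rng.normal(0, 0.01, size=(64, 64)))
        m[30:34, :] = 1.0
        w_b = binarize_detail(m)
        assert w_b[30:34, :].all()
        assert w_b.sum() == pytest.approx(4 * 64, abs=10)

    def test_scaling_invariance(self, rng):
        m = np.abs(rng.normal(size=(32, 32)))
        np.testing.assert_array_equal(binarize_detail(m), binarize_detail(m * 2.0))

    def test_matches_bruteforce_threshold(self, rng):
        m = np.abs(rng.normal(size=(32, 32)))
        lo, hi = m.min(), m.max()
        idx = np.clip(((m - lo) * (N_BINS / (hi - lo))).astype(int), 0, N_BINS - 1)
        k_oracle, _ = brute_force_otsu(np.bincount(idx.ravel(), minlength=N_BINS))
        np.testing.assert_array_equal(binarize_detail(m), idx > k_oracle)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            binarize_detail(np.full((4, 4), -1.0))


class TestBuildContourMask:
    def _disk_window(self, r=60):
        rr, cc = np.mgrid[0:256, 0:256]
        img = np.full((256, 256), 0.2)
        img[(rr - 128) ** 2 + (cc - 128) ** 2 <= r**2] = 0.9
        return img, (rr - 128) ** 2 + (cc - 128) ** 2 <= r**2

    def test_band_straddles_disk_contour(self):
        img, disk = self._disk_window()
        w_m = build_contour_mask(img, dilation_radius=5, border_margin=0)
        boundary = disk & ~ndimage.binary_erosion(disk)
        assert w_m[boundary].mean() > 0.95  # contour inside the band
        deep = ndimage.binary_erosion(disk, iterations=12)
        assert not w_m[deep].any()  # deep interior excluded

    def test_all_dark_window_empty(self):
        assert not build_contour_mask(np.zeros((256, 256))).any()

    def test_monotone_in_dilation_radius(self):
        img, _ = self._disk_window()
        m1 = build_contour_mask(img, dilation_radius=3, border_margin=0)
        m2 = build_contour_mask(img, dilation_radius=7, border_margin=0)
        assert (m1 <= m2).all()

    def test_border_margin_excluded(self):
        img, _ = self._disk_window(r=120)
        w_m = build_contour_mask(img, border_margin=16)
        assert not w_m[:16, :].any() and not w_m[:, -16:].any()


class TestApplyMask:
    def test_identity_and_annihilator(self, rng):
        w_b = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(apply_mask(w_b, np.ones((16, 16), bool)), w_b)
        assert not apply_mask(w_b, np.zeros((16, 16), bool)).any()

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pixelwise_and(self, seed):
        r = np.random.default_rng(seed)
        w_b = r.random((8, 8)) > 0.5
        w_m = r.random((8, 8)) > 0.5
        out = apply_mask(w_b, w_m)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == (w_b[i, j] and w_m[i, j])

    def test_idempotent_in_mask(self, rng):
        w_b = rng.random((32, 32)) > 0.4
        w_m = rng.random((32, 32)) > 0.4
        once = apply_mask(w_b, w_m)
        np.testing.assert_array_equal(apply_mask(once, w_m), once)

    def test_commutative(self, rng):
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        np.testing.assert_array_equal(apply_mask(a, b), apply_mask(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_mask(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def test_edge_window_subset_relations(rng):
    img = np.full((256, 256), 0.2)
    img[:, 100:] = 0.9
    img += rng.normal(0, 0.02, img.shape)
    m = np.abs(rng.normal(size=(256, 256)))
    ew = edge_window(m, img)
    assert not (ew.w_e & ~ew.w_b).any()  # W_e subset of W_b
    assert not (ew.w_e & ~ew.w_m).any()  # W_e subset of W_m


def test_dump_triptych_writes_png(tmp_path, rng):
    from pelvifrac.masking import dump_triptych

    img = np.full((256, 256), 0.2)
    img[:, 100:] = 0.9
    ew = edge_window(np.abs(rng.normal(size=(256, 256))), img)
    dump_triptych(ew, tmp_path / "trip.png")
    assert (tmp_path / "trip.png").exists()
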