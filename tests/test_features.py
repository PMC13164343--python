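"""Symbolic feature extractors against brute-force oracles and closed forms."""

import numpy as np
import pytest

from fdtaudit.features import (
    SymbolicFeatures,
    TumorMask,
    band_rows,
    border_edge_density,
    enhancement_variance,
    extract_all,
    segment_otsu,
    sellar_band_overlap,
)


def brute_force_otsu(img, nbins=256):
    """Maximize between-class variance over all histogram thresholds."""
    flat = np.asarray(img).ravel()
    lo, hi = flat.min(), flat.max()
    centers = lo + (np.arange(nbins) + 0.5) * (hi - lo) / nbins
    best_t, best_s = None, -1.0
    for t in centers:
        w0 = (flat <= t).mean()
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0, mu1 = flat[flat <= t].mean(), flat[flat > t].mean()
        s = w0 * w1 * (mu0 - mu1) ** 2
        if s > best_s:
            best_s, best_t = s, t
    return best_t


class TestSegmentOtsu:
    def test_bimodal_image_masks_bright_half(self):
        img = np.full((20, 20), 0.2)
        img[:, 10:] = 0.8
        mask = segment_otsu(img)
        assert np.array_equal(mask.mask, img == 0.8)
        # and the library threshold agrees with the brute-force oracle
        t = brute_force_otsu(img)
        assert 0.2 <= t < 0.8

    def test_constant_image_degenerate(self):
        mask = segment_otsu(np.full((16, 16), 0.5))
        assert mask.degenerate and mask.pixel_count == 0

    def test_threshold_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            img = rng.uniform(0, 1, size=(32, 32))
            mask = segment_otsu(img)
            t = brute_force_otsu(img)
            oracle_mask = img > t
            # both cut at an equivalent histogram boundary
            assert (mask.mask == oracle_mask).mean() > 0.99

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            segment_otsu(np.full((8, 8), 2.0))


class TestEnhancementVariance:
    def test_constant_region_zero(self):
        img = np.full((10, 10), 0.7)
        mask = segment_otsu(np.where(np.arange(100).reshape(10, 10) < 50, 0.1, 0.7))
        assert enhancement_variance(img, mask) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "a,b,expected", [(0.6, 1.0, 0.04), (0.5, 1.0, 0.0625)]
    )
    def test_two_level_closed_form(self, a, b, expected):
        img = np.full((10, 10), a)
        img[:, 5:] = b
        full = TumorMask(np.ones_like(img, dtype=bool))
        assert enhancement_variance(img, full) == pytest.approx(expected, abs=1e-12)

    def test_mixing_fraction_closed_form(self):
        # variance of a p/(1-p) two-level mix is p(1-p)(a-b)^2
        a, b, p = 0.55, 0.95, 0.3
        img = np.full((10, 10), a)
        img.ravel()[: int(p * 100)] = b
        full = TumorMask(np.ones_like(img, dtype=bool))
        expected = p * (1 - p) * (a - b) ** 2
        assert enhancement_variance(img, full) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_in_mask_permutation(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.5, 1.0, size=(12, 12))
        mask = TumorMask(np.ones_like(img, dtype=bool))
        v1 = enhancement_variance(img, mask)
        shuffled = img.copy().ravel()
        rng.shuffle(shuffled)
        v2 = enhancement_variance(shuffled.reshape(img.shape), mask)
        assert v1 == pytest.approx(v2)

    def test_shape_mismatch_errors(self):
        mask = segment_otsu(np.eye(4) * 0.9)
        with pytest.raises(ValueError):
            enhancement_variance(np.zeros((5, 5)), mask)


class TestSellarBandOverlap:
    def _mask_at_rows(self, h, rows):
        img = np.full((h, h), 0.1)
        for r in rows:
            img[r, :10] = 0.9
        return img, segment_otsu(img)

    def test_fully_inside_band(self):
        lo, hi = band_rows(100)
        img, mask = self._mask_at_rows(100, range(lo, hi))
        frac, _ = sellar_band_overlap(img, mask)
        assert frac == 1.0

    def test_fully_outside_band(self):
        img, mask = self._mask_at_rows(100, range(0, 10))
        frac, _ = sellar_band_overlap(img, mask)
        assert frac == 0.0

    def test_half_in_half_out(self):
        lo, _ = band_rows(100)
        img, mask = self._mask_at_rows(100, list(range(lo, lo + 3)) + [0, 1, 2])
        frac, _ = sellar_band_overlap(img, mask)
        assert frac == pytest.approx(0.5)

    def test_empty_mask_zero_with_centroid(self):
        img = np.full((50, 50), 0.3)
        frac, centroid = sellar_band_overlap(img, segment_otsu(img))
        assert frac == 0.0
        assert centroid == pytest.approx((24.5, 24.5))


class TestBorderEdgeDensity:
    def test_blank_image(self):
        assert border_edge_density(np.zeros((64, 64))) == 0.0

    def test_interior_rectangle_contributes_nothing(self):
        img = np.zeros((100, 100))
        img[30:60, 30:60] = 1.0  # edges live well inside the inner 80%
        assert border_edge_density(img) == 0.0

    def test_border_bar_density_matches_geometry(self):
        img = np.zeros((100, 100))
        img[3:6, 20:80] = 1.0  # 3px bar inside the top border band
        density = border_edge_density(img)
        band_area = 100 * 100 - 80 * 80
        expected = (2 * 60 + 6) / band_area  # two long edges + end caps
        assert density == pytest.approx(expected, abs=0.01)

    def test_invariant_under_horizontal_flip(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, size=(64, 64))
        assert border_edge_density(img) == pytest.approx(
            border_edge_density(img[:, ::-1])
        )


class TestExtractAll:
    def test_deterministic(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(0, 1, size=(64, 64))
        assert extract_all(img) == extract_all(img)

    def test_constant_slice_flagged(self):
        f = extract_all(np.full((64, 64), 0.2))
        assert "degenerate_mask" in f.flags
        assert f.enhancement_variance == 0.0 and f.mask_area == 0

    def test_feature_ranges(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            f = extract_all(rng.uniform(0, 1, size=(48, 48)))
            assert 0 <= f.enhancement_variance <= 0.25
            assert 0 <= f.sellar_band_overlap <= 1
            assert 0 <= f.border_edge_density <= 1


def test_batch_extraction_round_trip(tmp_path):
    from fdtaudit.io import save_slice, write_manifest
    from fdtaudit.features import extract_manifest

    img = np.zeros((64, 64))
    img[20:30, 20:30] = 0.9
    save_slice(img, tmp_path / "a.png")
    write_manifest([("a.png", "glioma")], tmp_path / "manifest.csv")
    n = extract_manifest(tmp_path / "manifest.csv", tmp_path / "features.csv")
    assert n == 1
    text = (tmp_path / "features.csv").read_text()
    assert text.splitlines()[0].startswith("slice_id")
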