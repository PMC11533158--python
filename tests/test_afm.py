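"""Image preprocessing chain and hexagon-area analysis."""

import numpy as np
import pytest

from starlattice.afm import (
    AFMImage,
    SortingThresholds,
    area_pdf,
    cap_percentiles,
    classify_hexagons,
    compute_sorting_thresholds,
    dynamic_cap,
    flatten_lines,
    hexagon_areas,
    otsu_foreground,
    preprocess,
)
from starlattice.network import enumerate_faces
from starlattice.synth import RenderParams, honeycomb_flake, mixed_lattice, render


class TestCapPercentiles:
    def test_lower_cap_value(self):
        img = AFMImage(np.arange(1, 1001, dtype=float).reshape(10, 100))
        out = cap_percentiles(img, lo=0.5, hi=99.99)
        lo_val = np.percentile(img.height, 0.5)
        assert out.height.min() == pytest.approx(lo_val)
        assert (out.height >= lo_val).all()

    def test_constant_image_unchanged(self):
        img = AFMImage(np.full((8, 8), 3.3))
        out = cap_percentiles(img)
        assert np.array_equal(out.height, img.height)

    def test_spike_clamped(self):
        h = np.zeros((50, 50))
        h[25, 25] = 1e6
        out = cap_percentiles(AFMImage(h))
        assert out.height.max() == pytest.approx(
            np.percentile(h, 99.99))

    def test_record_carries_convention(self):
        out = cap_percentiles(AFMImage(np.random.default_rng(0).random((5, 5))))
        assert out.record[-1]["interpolation"] == "linear"


class TestOtsu:
    def test_bimodal_separation(self):
        h = np.zeros((10, 10))
        h[:, 5:] = 10.0
        mask, t = otsu_foreground(AFMImage(h))
        assert 0 < t < 10
        assert mask.sum() == 50
        assert mask[:, 5:].all()

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(3)
        h = np.concatenate([rng.normal(0, 0.3, 600), rng.normal(2, 0.4, 400)])
        img = AFMImage(h.reshape(25, 40))
        _, t = otsu_foreground(img, nbins=256)
        # brute force: maximize between-class variance over histogram bins
        counts, edges = np.histogram(h, bins=256)
        centers = 0.5 * (edges[1:] + edges[:-1])
        best, best_t = -1, None
        for k in range(1, 256):
            w0, w1 = counts[:k].sum(), counts[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:k] * centers[:k]).sum() / w0
            m1 = (counts[k:] * centers[k:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, centers[k - 1:k + 1].mean()
        assert t == pytest.approx(best_t, abs=(edges[1] - edges[0]))

    def test_inverted_image_complementary_mask(self):
        rng = np.random.default_rng(5)
        h = np.concatenate([rng.normal(0, 0.2, 500), rng.normal(3, 0.2, 500)])
        img = AFMImage(h.reshape(25, 40))
        m1, _ = otsu_foreground(img)
        m2, _ = otsu_foreground(AFMImage(-img.height))
        assert (m1 == ~m2).mean() > 0.99

    def test_constant_image_flagged(self):
        mask, t = otsu_foreground(AFMImage(np.ones((5, 5))))
        assert t is None and not mask.any()


class TestFlattenLines:
    def _ridged_tilt(self, rng):
        """Per-line linear ramp + lattice-like ridges, with ground truth."""
        ny, nx = 60, 80
        x = np.arange(nx)
        bg = np.empty((ny, nx))
        for iy in range(ny):
            bg[iy] = 0.01 * (iy - 30) * (x - 40) / 40
        ridges = np.zeros((ny, nx))
        ridges[::6] = 2.0
        return bg, ridges

    def test_known_background_removed(self):
        rng = np.random.default_rng(0)
        bg, ridges = self._ridged_tilt(rng)
        img = AFMImage(bg + ridges)
        mask = ridges > 0
        out = flatten_lines(img, mask, degree=1)
        resid = out.height[~mask]
        assert np.sqrt((resid ** 2).mean()) < 0.02  # < 1% of ridge height

    def test_zero_image_stays_zero(self):
        out = flatten_lines(AFMImage(np.zeros((10, 10))),
                            np.zeros((10, 10), bool))
        assert np.allclose(out.height, 0)

    def test_idempotent_on_flattened(self):
        rng = np.random.default_rng(1)
        bg, ridges = self._ridged_tilt(rng)
        img = AFMImage(bg + ridges)
        once = flatten_lines(img, ridges > 0, degree=1, passes=2)
        again = flatten_lines(once, ridges > 0, degree=1, passes=1)
        assert np.abs(again.height - once.height).max() < 0.02

    def test_all_foreground_errors(self):
        with pytest.raises(ValueError):
            flatten_lines(AFMImage(np.ones((5, 5))), np.ones((5, 5), bool))


class TestDynamicCap:
    def _base(self):
        rng = np.random.default_rng(2)
        h = np.zeros((40, 60))
        h[::5] = 2.0  # foreground rows
        return h

    def test_streak_clamped_other_lines_untouched(self):
        h = self._base()
        h[7, 30] = 50.0  # tall streak artifact on a sparse line
        img = AFMImage(h)
        mask = h > 1.0
        out = dynamic_cap(img, mask)
        assert out.height[7, 30] < 50.0
        assert np.array_equal(out.height[5], h[5])

    def test_within_range_unchanged(self):
        h = self._base()
        out = dynamic_cap(AFMImage(h), h > 1.0)
        assert np.allclose(out.height[h <= 2.0], h[h <= 2.0])

    def test_negative_background_set_to_zero(self):
        h = self._base()
        h[2, 2] = -0.7
        out = dynamic_cap(AFMImage(h), h > 1.0)
        assert out.height[2, 2] == 0.0

    def test_no_foreground_pass_through(self):
        h = np.zeros((5, 5))
        out = dynamic_cap(AFMImage(h), np.zeros((5, 5), bool))
        assert out.record[-1].get("no_foreground")


class TestHexagonAreas:
    def test_regular_hexagon_closed_form(self):
        gt = honeycomb_flake(1, edge_nm=30.0)
        areas = hexagon_areas(gt.faces)
        assert len(areas) == 1
        assert areas[0] == pytest.approx(1.5 * np.sqrt(3) * 30.0 ** 2, rel=1e-9)

    def test_area_scales_quadratically(self):
        a1 = hexagon_areas(honeycomb_flake(2, edge_nm=20.0).faces)
        a2 = hexagon_areas(honeycomb_flake(2, edge_nm=40.0).faces)
        assert np.mean(a2) == pytest.approx(4 * np.mean(a1), rel=1e-9)

    def test_mixed_lattice_modes_separate(self):
        short = mixed_lattice(30.0, 40.0, 0.0, size=6)
        long_ = mixed_lattice(30.0, 40.0, 1.0, size=6)
        assert np.mean(hexagon_areas(long_.faces)) > \
            1.5 * np.mean(hexagon_areas(short.faces))


class TestClassifyHexagons:
    def test_three_way_classification(self):
        th = SortingThresholds(short_cut=300, long_cut=500)
        assert classify_hexagons([250, 600, 400], th) == \
            ["short", "long", "intermediate"]

    def test_thresholds_from_references(self):
        rng = np.random.default_rng(0)
        short = rng.normal(2300, 100, 400)
        long_ = rng.normal(4100, 120, 400)
        th = compute_sorting_thresholds(short, long_)
        assert th.short_cut == pytest.approx(np.percentile(short, 95))
        assert th.long_cut == pytest.approx(np.percentile(long_, 5))
        assert not th.overlapping

    def test_overlapping_references_flagged(self):
        th = SortingThresholds(short_cut=520, long_cut=480)
        assert th.overlapping
        assert classify_hexagons([500], th) == ["intermediate"]

    def test_empty_references_error(self):
        with pytest.raises(ValueError):
            compute_sorting_thresholds([], [1.0])


class TestAreaPdf:
    def test_normalization(self):
        rng = np.random.default_rng(1)
        grid, dens, method = area_pdf(rng.normal(1000, 50, 300))
        assert method.startswith("kde")
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_unimodal_sample_single_mode(self):
        rng = np.random.default_rng(2)
        grid, dens, _ = area_pdf(rng.normal(1000, 50, 500))
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(dens, prominence=dens.max() * 0.1)
        assert len(peaks) == 1

    def test_histogram_fallback_below_ten(self):
        _, _, method = area_pdf([1.0, 2.0, 3.0])
        assert method == "histogram"

    def test_mixture_fills_the_gap_between_modes(self):
        rng = np.random.default_rng(3)
        short = rng.normal(2300, 80, 300)
        long_ = rng.normal(4100, 90, 300)
        mid = 0.5 * (2300 + 4100)
        grid = np.linspace(1800, 4700, 600)
        _, d_s, _ = area_pdf(short, grid=grid)
        _, d_l, _ = area_pdf(long_, grid=grid)
        _, d_m, _ = area_pdf(np.concatenate([short, long_]), grid=grid)
        sel = np.abs(grid - mid) < 300
        assert d_m[sel].sum() > d_s[sel].sum()
        assert d_m[sel].sum() > d_l[sel].sum()


class TestPreprocessPipeline:
    def test_background_median_zero_after_preprocess(self):
        gt = honeycomb_flake(2)
        img = render(gt, RenderParams(seed=3))
        pre = preprocess(img)
        mask, _ = otsu_foreground(pre)
        assert abs(np.median(pre.height[~mask])) < 0.05

    def test_deterministic_given_input(self):
        gt = honeycomb_flake(2)
        img = render(gt, RenderParams(seed=4))
        p1 = preprocess(img)
        p2 = preprocess(img)
        assert np.array_equal(p1.height, p2.height)
        assert p1.record == p2.record
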