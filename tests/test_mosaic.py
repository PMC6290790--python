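"""Demosaicking: mosaic splitting, both reconstruction routes, completeness."""

import numpy as np
import pytest

from decomb.centres import CentreMap
from decomb.correct import ScatteredInterpolator
from decomb.metrics import asr
from decomb.mosaic import (
    CFAPattern,
    CentreBasedDemosaicker,
    CentreSpectra,
    centre_based_demosaick,
    check_sampling_ratio,
    demosaick_then_filter,
    interpolate_centre_spectra,
    nearest_band_pixel,
    simple_demosaick,
    split_mosaic,
)
from decomb.synthetic import SceneSpectrum, simulate_ms_capture, make_target

P3 = CFAPattern.standard(3)


def centre_map_from(points, D=9):
    pts = np.asarray(points, dtype=float)
    return CentreMap(centres=pts, scores=np.zeros(len(pts)), D=D)


class TestCFAPattern:
    def test_tile_must_hold_each_band_once(self):
        with pytest.raises(ValueError, match="exactly once"):
            CFAPattern(tile=np.array([[0, 1], [1, 2]]))

    def test_band_index_map_tiles_with_offset(self):
        p = CFAPattern(tile=np.arange(4).reshape(2, 2), offset=(1, 0))
        m = p.band_index_map((4, 4))
        np.testing.assert_array_equal(m[0, :2], [2, 3])
        np.testing.assert_array_equal(m[1, :2], [0, 1])


class TestSamplingRatio:
    def test_valid_ratio(self):
        assert check_sampling_ratio(P3, 5) == pytest.approx(0.6)
        assert check_sampling_ratio(CFAPattern.standard(2), 10) == pytest.approx(0.2)

    def test_boundary_is_invalid(self):
        with pytest.warns(UserWarning, match="T = L/D"):
            assert check_sampling_ratio(P3, 3) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="T = L/D"):
            check_sampling_ratio(P3, 3, strict=True)


class TestSplitMosaic:
    def test_constant_raw(self):
        bands = split_mosaic(np.full((6, 6), 4.0), P3)
        for b in bands:
            np.testing.assert_allclose(b.compressed(), 4.0)

    def test_each_band_ninth_of_pixels(self, rng):
        raw = rng.uniform(0, 1, (9, 9))
        bands = split_mosaic(raw, P3)
        for b in bands:
            assert b.count() == 9

    def test_roundtrip_reassembly(self, rng):
        raw = rng.uniform(0, 1, (12, 12))
        bands = split_mosaic(raw, P3)
        rebuilt = np.zeros_like(raw)
        for b in bands:
            rebuilt[~b.mask] = b.data[~b.mask]
        np.testing.assert_array_equal(rebuilt, raw)


class TestSimpleDemosaick:
    def test_constant_raw_constant_cube(self):
        cube = simple_demosaick(np.full((9, 9), 7.0), P3)
        np.testing.assert_allclose(cube.data, 7.0)

    def test_planar_ramp_recovered_in_interior(self):
        yy, xx = np.mgrid[0:18, 0:18].astype(float)
        raw = 2.0 * xx + 3.0 * yy + 5.0
        cube = simple_demosaick(raw, P3)
        for k in range(9):
            np.testing.assert_allclose(
                cube[k][3:-3, 3:-3], raw[3:-3, 3:-3], atol=1e-9
            )

    def test_flat_scene_band_means_match_spectrum(self, small_comb):
        spectrum = SceneSpectrum(np.linspace(2.0, 10.0, 9))
        target = make_target(
            "uniform", {"value": 200.0}, blur_sigma=0, shape=small_comb.shape
        )
        raw, truth = simulate_ms_capture(
            target, small_comb, spectrum, P3, noise_sigma=0.0, dark_level=0.0
        )
        cube = simple_demosaick(raw, P3)
        ratio = cube.band_means() / truth.mean(axis=(1, 2))
        np.testing.assert_allclose(ratio, 1.0, atol=0.02)


class TestDemosaickThenFilter:
    def test_gaussian_on_constant(self):
        cube = demosaick_then_filter(np.full((18, 18), 3.0), P3, "gaussian", 2)
        np.testing.assert_allclose(cube.data, 3.0)

    def test_physical_equals_simple_demosaick(self, rng):
        raw = rng.uniform(0, 1, (18, 18))
        a = demosaick_then_filter(raw, P3, "physical")
        b = simple_demosaick(raw, P3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_filtering_before_demosaicking_corrupts_spectra(self, small_comb):
        from decomb.correct import gaussian_decomb

        spectrum = SceneSpectrum(np.linspace(1.0, 9.0, 9))
        target = make_target(
            "uniform", {"value": 200.0}, blur_sigma=0, shape=small_comb.shape
        )
        raw, _ = simulate_ms_capture(
            target, small_comb, spectrum, P3, noise_sigma=0.0, dark_level=0.0
        )
        good = demosaick_then_filter(raw, P3, "gaussian", 5)
        bad = simple_demosaick(gaussian_decomb(raw, 5), P3)
        e = spectrum.band_intensities
        assert asr(bad, e) > 10 * asr(good, e)


class TestCentreBasedDemosaick:
    def test_nearest_neighbour_within_chebyshev_L_minus_1(self):
        # exhaustive over all 9 centre phases of the super-pixel
        shape = (18, 18)
        for py in range(6, 9):
            for px in range(6, 9):
                for k in range(9):
                    pixels, dist = nearest_band_pixel((px, py), k, P3, shape)
                    for cx, cy in pixels:
                        assert max(abs(cx - px), abs(cy - py)) <= P3.L - 1
                    assert dist <= np.sqrt(2) * (P3.L - 1)

    def test_nearest_matches_exhaustive_search(self, rng):
        shape = (45, 45)
        p = P3.band_index_map(shape)
        for _ in range(100):
            px, py = rng.integers(0, 45, 2)
            k = int(rng.integers(0, 9))
            pixels, dist = nearest_band_pixel((int(px), int(py)), k, P3, shape)
            ys, xs = np.nonzero(p == k)
            d_all = np.hypot(xs - px, ys - py)
            assert dist == pytest.approx(d_all.min())
            best = set(zip(xs[d_all <= d_all.min() + 1e-12].tolist(),
                           ys[d_all <= d_all.min() + 1e-12].tolist()))
            assert set(pixels) == best

    def test_centre_pixel_supplies_own_band(self, rng):
        raw = rng.uniform(10, 20, (18, 18))
        cmap = centre_map_from([[4, 7], [10, 13], [7, 4]], D=9)
        spectra = centre_based_demosaick(raw, P3, cmap)
        p = P3.band_index_map(raw.shape)
        for m, (x, y) in enumerate(cmap.centres):
            k = p[int(y), int(x)]
            assert spectra.values[m, k] == raw[int(y), int(x)]

    def test_constant_raw_constant_spectra(self):
        raw = np.full((18, 18), 6.0)
        cmap = centre_map_from([[5, 5], [12, 6], [8, 12]], D=9)
        spectra = centre_based_demosaick(raw, P3, cmap)
        np.testing.assert_allclose(spectra.values, 6.0)

    def test_complete_when_ratio_valid(self, rng):
        raw = rng.uniform(0, 1, (27, 27))
        pts = rng.uniform(4, 22, (12, 2))
        # enforce >D separation so the map is a valid CentreMap
        keep = []
        for i, p in enumerate(pts):
            if all(np.hypot(*(p - pts[j])) > 9 for j in keep):
                keep.append(i)
        cmap = centre_map_from(pts[keep], D=9)
        spectra = centre_based_demosaick(raw, P3, cmap)
        assert spectra.is_complete()

    def test_refuses_invalid_sampling_ratio(self, rng):
        raw = rng.uniform(0, 1, (18, 18))
        cmap = centre_map_from([[5, 5], [12, 6], [8, 12]], D=3)
        with pytest.raises(ValueError, match="T = L/D"):
            centre_based_demosaick(raw, P3, cmap)


class TestInterpolateCentreSpectra:
    def _spectra(self, values, pts):
        return CentreSpectra(values=values, centre_map=centre_map_from(pts))

    def test_constant_spectra_constant_cube(self):
        pts = [[5.0, 5.0], [25.0, 6.0], [14.0, 25.0]]
        cube = interpolate_centre_spectra(
            self._spectra(np.full((3, 9), 2.5), pts), (30, 30)
        )
        np.testing.assert_allclose(cube.data, 2.5, atol=1e-12)

    def test_per_band_planes_exact_inside_hull(self, rng):
        pts = rng.uniform(0, 29, (25, 2))
        keep = []
        for i, p in enumerate(pts):
            if all(np.hypot(*(p - pts[j])) > 9 for j in keep):
                keep.append(i)
        pts = pts[keep]
        coef = rng.uniform(-1, 1, (9, 3))
        values = np.stack(
            [a * pts[:, 0] + b * pts[:, 1] + c for a, b, c in coef], axis=1
        )
        interp = ScatteredInterpolator(pts, (30, 30))
        cube = interpolate_centre_spectra(
            self._spectra(values, pts), (30, 30), interpolator=interp
        )
        yy, xx = np.mgrid[0:30, 0:30]
        for k, (a, b, c) in enumerate(coef):
            expected = a * xx + b * yy + c
            np.testing.assert_allclose(
                cube[k][interp.valid_mask], expected[interp.valid_mask], atol=1e-9
            )

    def test_shared_lut_bitwise_equals_per_band(self, rng):
        pts = np.array([[5.0, 5.0], [25.0, 6.0], [14.0, 25.0], [27.0, 27.0]])
        values = rng.uniform(0, 1, (4, 9))
        spectra = self._spectra(values, pts)
        shared = interpolate_centre_spectra(spectra, (30, 30))
        for k in range(9):
            per_band = ScatteredInterpolator(pts, (30, 30))(values[:, k])
            np.testing.assert_array_equal(shared[k], per_band)


class TestCentreBasedDemosaicker:
    def test_fit_transform_pipeline(self, small_comb):
        spectrum = SceneSpectrum(np.linspace(1.0, 9.0, 9))
        flat = make_target(
            "uniform", {"value": 255.0}, blur_sigma=0, shape=small_comb.shape
        )
        cal_raw, _ = simulate_ms_capture(
            flat, small_comb, SceneSpectrum(np.full(9, 5.0)), P3,
            noise_sigma=0.0, dark_level=0.0,
        )
        est = CentreBasedDemosaicker(pattern=P3, D=9, I_min=20.0).fit(cal_raw)
        raw, _ = simulate_ms_capture(
            flat, small_comb, spectrum, P3, noise_sigma=0.0, dark_level=0.0
        )
        cube = est.transform(raw)
        assert cube.n_bands == 9
        # reconstructed spectrum proportional to the scene spectrum
        assert asr(cube, spectrum.band_intensities) < 1e-3

    def test_invalid_ratio_rejected_at_fit(self, rng):
        with pytest.raises(ValueError, match="T = L/D"):
            CentreBasedDemosaicker(pattern=P3, D=3).fit(rng.uniform(0, 1, (18, 18)))
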