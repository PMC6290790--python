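"""Generator invariants: comb decomposition, masking rules, reproducibility."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from decomb.mosaic import CFAPattern
from decomb.synthetic import (
    BINARISE_THRESHOLD,
    CombMask,
    CombSpec,
    FibreletMask,
    SceneSpectrum,
    apply_cfa,
    apply_comb,
    fibrelet_means,
    generate_comb,
    make_target,
    simulate_defocus,
)


class TestGenerateComb:
    def test_single_fibrelet_no_jitter(self):
        spec = CombSpec(
            image_side=40, n_fibrelets=1, mean_diameter=10,
            diameter_jitter=0, position_jitter=0, mask_blur_sigma=0, seed=0,
        )
        comb = generate_comb(spec)
        assert comb.n_fibrelets == 1
        # a single hard-edged disc of the requested radius
        area = (comb.transmission > 0.5).sum()
        assert area == pytest.approx(np.pi * 25, rel=0.1)
        assert len(comb.true_centres) == 1

    def test_no_jitter_is_seed_independent(self):
        kw = dict(
            image_side=80, n_fibrelets=20, diameter_jitter=0, position_jitter=0
        )
        a = generate_comb(CombSpec(seed=1, **kw))
        b = generate_comb(CombSpec(seed=99, **kw))
        np.testing.assert_array_equal(a.transmission, b.transmission)
        np.testing.assert_array_equal(a.true_centres, b.true_centres)

    def test_deterministic_given_seed(self):
        spec = CombSpec(image_side=100, n_fibrelets=50, seed=7)
        a, b = generate_comb(spec), generate_comb(spec)
        np.testing.assert_array_equal(a.transmission, b.transmission)
        np.testing.assert_array_equal(a.true_centres, b.true_centres)

    def test_supports_disjoint_and_spaced(self):
        spec = CombSpec(image_side=140, n_fibrelets=100, mean_diameter=8, cladding_gap=2, seed=2)
        comb = generate_comb(spec)
        assert comb.n_fibrelets == 100
        # brute-force pairwise centre distances against the jitter bound
        jitter_amp = spec.position_jitter * spec.pitch
        min_dist = pdist(comb.true_centres).min()
        assert min_dist >= spec.pitch - 2 * jitter_amp - 1e-9
        # binarised supports pairwise disjoint
        occupancy = np.zeros(comb.shape, dtype=int)
        for fm in comb.fibrelets:
            occupancy[fm.slices] += fm.support().astype(int)
        assert occupancy.max() <= 1

    def test_decomposition_sums_to_transmission(self, small_comb):
        total = np.zeros(small_comb.shape)
        for fm in small_comb.fibrelets:
            total[fm.slices] += fm.patch
        np.testing.assert_allclose(total, small_comb.transmission, atol=1e-12)

    def test_centres_inside_own_mask(self, small_comb):
        for fm, (x, y) in zip(small_comb.fibrelets, small_comb.true_centres):
            ys, xs = fm.slices
            iy, ix = int(round(y)) - ys.start, int(round(x)) - xs.start
            assert fm.support()[iy, ix]

    def test_count_scales_inversely_with_magnification_squared(self):
        counts = {}
        for m in (0.7, 1.0, 1.3):
            comb = generate_comb(CombSpec(image_side=300, magnification=m, seed=5))
            counts[m] = comb.n_fibrelets
        for m in (0.7, 1.3):
            assert counts[m] / counts[1.0] == pytest.approx(1.0 / m**2, rel=0.15)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_comb(CombSpec(image_side=40, n_fibrelets=10_000))
        with pytest.raises(ValueError):
            CombSpec(mean_diameter=-1)
        with pytest.raises(ValueError):
            CombSpec(position_jitter=0.6)


class TestMakeTarget:
    def test_uniform_is_constant(self):
        t = make_target("uniform", {"value": 100.0}, blur_sigma=0, noise_sigma=0)
        np.testing.assert_array_equal(t.image, 100.0)

    def test_bar_target_square_wave_full_modulation(self):
        t = make_target(
            "bar_target",
            {"spacings": [20, 40, 80], "phases": 1},
            blur_sigma=0, noise_sigma=0, shape=(120, 120),
        )
        el = t.elements[0]
        rows = t.image[el.rows[0] : el.rows[1]]
        assert set(np.unique(rows)) == {0.0, 200.0}
        # exact square wave: period 20, half duty
        assert rows[0, :20].tolist() == [200.0] * 10 + [0.0] * 10

    def test_bright_region_mean(self):
        t = make_target("bright_region", None, blur_sigma=0, noise_sigma=0, shape=(64, 64))
        x0, y0, x1, y1 = t.geometry["region"]
        assert t.image[y0:y1, x0:x1].mean() == pytest.approx(156.0)
        assert t.image[0, 0] == pytest.approx(117.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown target kind"):
            make_target("speckle")

    def test_bar_target_needs_three_spacings(self):
        with pytest.raises(ValueError, match="3 distinct"):
            make_target("bar_target", {"spacings": [10, 10, 10]})


def _two_pixel_comb():
    """One fibrelet with graded mask {0.5, 1.0} on two pixels."""
    patch = np.array([[0.5, 1.0]])
    mask = np.zeros((4, 4))
    mask[1, 1:3] = patch
    fm = FibreletMask(slices=(slice(1, 2), slice(1, 3)), patch=patch)
    return CombMask(transmission=mask, fibrelets=[fm], true_centres=np.array([[2.0, 1.0]]))


class TestApplyComb:
    def test_hand_masking_example(self):
        comb = _two_pixel_comb()
        target = np.zeros((4, 4))
        target[1, 1:3] = [10.0, 20.0]
        out = apply_comb(target, comb, noise_sigma=0.0)
        # per-fibrelet mean M = (10+20)/2 = 15, painted through {0.5, 1.0}
        assert out[1, 1] == pytest.approx(7.5)
        assert out[1, 2] == pytest.approx(15.0)
        assert fibrelet_means(target, comb)[0] == pytest.approx(15.0)

    def test_binarisation_threshold_is_strict(self):
        patch = np.array([[BINARISE_THRESHOLD, 1.0]])
        fm = FibreletMask(slices=(slice(0, 1), slice(0, 2)), patch=patch)
        comb = CombMask(
            transmission=np.pad(patch, ((0, 1), (0, 0))),
            fibrelets=[fm],
            true_centres=np.array([[1.0, 0.0]]),
        )
        target = np.array([[100.0, 40.0], [0.0, 0.0]])
        out = apply_comb(target, comb, noise_sigma=0.0)
        # pixel at exactly the threshold is excluded from the mean
        assert out[0, 1] == pytest.approx(40.0)

    def test_uniform_target_binary_comb(self):
        patch = np.array([[1.0, 1.0], [1.0, 0.0]])
        fm = FibreletMask(slices=(slice(0, 2), slice(0, 2)), patch=patch)
        comb = CombMask(
            transmission=patch.copy(), fibrelets=[fm], true_centres=np.array([[0.0, 0.0]])
        )
        out = apply_comb(np.full((2, 2), 37.0), comb, noise_sigma=0.0)
        np.testing.assert_allclose(out, 37.0 * patch)

    def test_per_fibrelet_mean_conserved(self, small_comb):
        target = make_target(
            "bar_target", {"spacings": [16, 24, 40], "phases": 1},
            blur_sigma=1.0, shape=small_comb.shape,
        )
        out = apply_comb(target, small_comb, noise_sigma=0.0)
        means = fibrelet_means(target, small_comb)
        for fm, m in zip(small_comb.fibrelets[::7], means[::7]):
            sup = fm.support()
            expected = m * fm.patch[sup].mean()
            assert out[fm.slices][sup].mean() == pytest.approx(expected, rel=1e-9)

    def test_degenerate_fibrelet_flagged(self):
        patch = np.full((1, 1), 0.05)
        fm = FibreletMask(slices=(slice(0, 1), slice(0, 1)), patch=patch)
        comb = CombMask(
            transmission=patch.copy(), fibrelets=[fm], true_centres=np.array([[0.0, 0.0]])
        )
        with pytest.warns(UserWarning, match="empty binarised support"):
            apply_comb(np.ones((1, 1)), comb, noise_sigma=0.0)

    def test_noise_reproducible(self, small_comb):
        t = make_target("uniform", shape=small_comb.shape)
        a = apply_comb(t, small_comb, noise_sigma=2.0, seed=9)
        b = apply_comb(t, small_comb, noise_sigma=2.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestApplyCFA:
    def test_identical_bands_make_pattern_invisible(self, rng):
        img = rng.uniform(0, 100, (12, 12))
        stack = np.repeat(img[None], 9, axis=0)
        raw = apply_cfa(stack, CFAPattern.standard(3), dark_level=0.0)
        np.testing.assert_allclose(raw, img)

    def test_constant_bands_tile_periodically(self):
        consts = np.arange(1.0, 10.0)
        stack = consts[:, None, None] * np.ones((9, 9, 9))
        raw = apply_cfa(stack, CFAPattern.standard(3), dark_level=0.0)
        np.testing.assert_allclose(raw[:3, :3], consts.reshape(3, 3))
        np.testing.assert_allclose(raw[3:6, 3:6], consts.reshape(3, 3))

    def test_composition_with_comb_at_centre_pixels(self, small_comb):
        spectrum = SceneSpectrum(np.linspace(1.0, 9.0, 9))
        pattern = CFAPattern.standard(3)
        scene = np.full(small_comb.shape, 200.0)
        comb_img = apply_comb(scene, small_comb, noise_sigma=0.0)
        scale = spectrum.band_intensities / spectrum.band_intensities.max()
        raw = apply_cfa(comb_img[None] * scale[:, None, None], pattern, dark_level=0.0)
        p = pattern.band_index_map(small_comb.shape)
        for x, y in small_comb.true_centres[::11]:
            px, py = int(round(x)), int(round(y))
            k = p[py, px]
            assert raw[py, px] == pytest.approx(scale[k] * comb_img[py, px])

    def test_pattern_must_cover_stack(self):
        with pytest.raises(ValueError, match="missing"):
            apply_cfa(np.ones((4, 6, 6)), CFAPattern.standard(3))


class TestSceneSpectrum:
    def test_derivation_from_tables(self):
        g = np.array([1.0, 2.0, 0.5])
        r = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 2.0]])
        s = SceneSpectrum.from_tables(g, r)
        np.testing.assert_allclose(s.band_intensities, [1.0, 2.5])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            SceneSpectrum(np.array([1.0, -0.1]))


class TestSimulateDefocus:
    def test_r_mapping(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        _, r = simulate_defocus(img, 5.0)
        assert r == 10.0

    def test_zero_displacement_identity(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out, r = simulate_defocus(img, 0.0)
        assert r == 0.0
        np.testing.assert_array_equal(out, img)

    def test_sign_symmetric(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        out_p, r_p = simulate_defocus(img, 5.0)
        out_m, r_m = simulate_defocus(img, -5.0)
        assert r_p == r_m
        np.testing.assert_array_equal(out_p, out_m)
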