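import math

import numpy as np
import pytest

from _oracles import (
    dilate_disk,
    feret_all_pairs,
    fill_and_erode,
    grey_opening_ball,
    yen_cut_scan,
)
from punctavol.imgio import PlaneImage
from punctavol.mncount import (
    MotorNeuronConfig,
    SectionSeries,
    analyze_particles,
    binary_cleanup,
    call_positives,
    count_motor_neurons,
    enhance_contrast,
    estimate_background,
    expand_by_feret,
    feret_diameter,
    normalize_per_mm,
    rolling_ball,
    yen_cut_from_counts,
    yen_threshold,
)
from punctavol.synthgen import SpinalConfig, generate_spinal_image


class TestEnhanceContrast:
    def test_zero_saturation_full_range_float_is_rescaled_identity(self):
        img = PlaneImage(np.linspace(0, 1, 100).reshape(10, 10))
        out = enhance_contrast(img, saturated_fraction=0.0)
        np.testing.assert_allclose(out.data, img.data, atol=1e-12)

    def test_ramp_clip_bounds_match_sorted_pixel_oracle(self):
        ramp = np.arange(1000, dtype=float).reshape(20, 50)
        out = enhance_contrast(PlaneImage(ramp), saturated_fraction=0.002,
                               normalize=False)
        # oracle: linear interpolation on the sorted pixel vector
        v = np.sort(ramp.ravel())
        n = len(v)

        def q(frac):
            pos = frac * (n - 1)
            lo, hi = int(math.floor(pos)), int(math.ceil(pos))
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        lo, hi = q(0.001), q(0.999)
        assert out.data.min() == pytest.approx(lo)
        assert out.data.max() == pytest.approx(hi)

    def test_constant_image_unchanged(self):
        img = PlaneImage(np.full((5, 5), 7.0))
        out = enhance_contrast(img)
        np.testing.assert_array_equal(out.data, img.data)

    def test_integer_image_normalizes_to_dtype_range(self):
        img = PlaneImage(np.arange(256, dtype=np.uint8).reshape(16, 16))
        out = enhance_contrast(img, saturated_fraction=0.0, normalize=True)
        assert out.data.min() == pytest.approx(0)
        assert out.data.max() == pytest.approx(255)


class TestRollingBall:
    def test_constant_image_gives_zero(self):
        out = rolling_ball(PlaneImage(np.full((32, 32), 40.0)), radius=5)
        np.testing.assert_allclose(out.data, 0.0)

    def test_peak_on_flat_background_degenerate_radius(self):
        img = np.full((64, 64), 10.0)
        img[30:33, 30:33] = 110.0
        out = rolling_ball(PlaneImage(img), radius=100)  # radius > both dims
        assert out.data[31, 31] == pytest.approx(100.0, abs=1)
        assert out.data[0, 0] == pytest.approx(0.0)

    def test_matches_brute_force_opening(self, rng):
        from scipy import ndimage as ndi

        img = ndi.gaussian_filter(rng.random((24, 24)) * 50, 2) + 5
        img[10:13, 8:11] += 80  # a peak the ball cannot enter
        out = rolling_ball(PlaneImage(img), radius=6)
        expected = np.clip(img - grey_opening_ball(img, 6), 0, None)
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_bounds(self, rng):
        img = rng.random((20, 20)) * 100
        out = rolling_ball(PlaneImage(img), radius=4)
        assert (out.data >= 0).all()
        assert (out.data <= img + 1e-9).all()

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball(PlaneImage(np.zeros((4, 4))), radius=0)


class TestYen:
    def test_two_level_image_threshold_strictly_between(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        t = yen_threshold(PlaneImage(img))
        assert 10 < t < 200
        assert ((img >= t) == (img == 200)).all()

    def test_matches_exhaustive_scan_on_small_histograms(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 50, size=8)
            if counts.sum() == 0 or (counts > 0).sum() < 2:
                continue
            assert yen_cut_from_counts(counts) == yen_cut_scan(counts)

    def test_invariant_under_count_scaling(self, rng):
        counts = rng.integers(1, 30, size=16)
        assert yen_cut_from_counts(counts) == yen_cut_from_counts(counts * 7)

    def test_constant_image_is_error(self):
        with pytest.raises(ValueError):
            yen_threshold(PlaneImage(np.full((4, 4), 3.0)))

    def test_close_to_skimage_reference(self, rng):
        # independent cross-check: thresholds agree to within one bin width
        from skimage.filters import threshold_yen as sk_yen

        img = np.concatenate([rng.normal(30, 5, 600), rng.normal(160, 10, 400)])
        img = img.reshape(40, 25)
        ours = yen_threshold(PlaneImage(img), n_bins=256)
        bin_width = (img.max() - img.min()) / 256
        assert abs(ours - sk_yen(img, nbins=256)) <= 2 * bin_width


class TestCleanup:
    def test_annulus_fills_then_erodes(self, make_disk):
        outer = make_disk((32, 32), (16, 16), 10)
        inner = make_disk((32, 32), (16, 16), 4)
        annulus = outer & ~inner
        out = binary_cleanup(annulus)
        np.testing.assert_array_equal(out, fill_and_erode(annulus))
        assert out[16, 16]  # hole is gone

    def test_empty_stays_empty(self):
        assert not binary_cleanup(np.zeros((8, 8), dtype=bool)).any()

    def test_solid_disk_area_strictly_decreases(self, make_disk):
        disk = make_disk((32, 32), (16, 16), 10)
        out = binary_cleanup(disk)
        assert 0 < out.sum() < disk.sum()

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((16, 16)) > 0.55
            np.testing.assert_array_equal(binary_cleanup(mask), fill_and_erode(mask))


class TestParticles:
    def test_disk_is_round_and_retained(self, make_disk):
        mask = make_disk((32, 32), (16, 16), 10)
        parts = analyze_particles(mask, pixel_size=1.0)
        assert len(parts) == 1
        assert 0.8 <= parts[0].circularity <= 1.0

    def test_line_rejected_by_circularity(self):
        mask = np.zeros((8, 70), dtype=bool)
        mask[4, 5:65] = True
        assert analyze_particles(mask, pixel_size=1.0) == []
        # retained when the gate is opened
        assert len(analyze_particles(mask, pixel_size=1.0, circ_range=(0.0, 1.0))) == 1

    def test_min_size_in_calibrated_units(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px²; at 0.3 µm/px => 0.36 µm² < 0.5
        assert analyze_particles(mask, pixel_size=0.3, min_size=0.5,
                                 circ_range=(0.0, 1.0)) == []
        assert len(analyze_particles(mask, pixel_size=None, min_size=0.5,
                                     circ_range=(0.0, 1.0))) == 1  # 4 px² >= 0.5

    def test_eight_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True  # touch at a corner
        parts = analyze_particles(mask, min_size=0.0, circ_range=(0.0, 1.0))
        assert len(parts) == 1


class TestFeret:
    def test_two_pixel_example(self):
        # corners of (0,0) and (3,4) reach from (0,0) to (4,5)
        assert feret_diameter([(0, 0), (3, 4)], pixel_size=1.0) == pytest.approx(
            math.sqrt(41))

    def test_single_pixel_is_diagonal(self):
        assert feret_diameter([(5, 5)]) == pytest.approx(math.sqrt(2))

    def test_matches_all_pairs_oracle_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 51))
            pixels = {(int(y), int(x)) for y, x in rng.integers(0, 30, size=(n, 2))}
            assert feret_diameter(list(pixels)) == pytest.approx(
                feret_all_pairs(pixels))

    def test_pixel_size_scales_linearly(self):
        base = feret_diameter([(0, 0), (0, 9)])
        assert feret_diameter([(0, 0), (0, 9)], pixel_size=0.5) == pytest.approx(base / 2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            feret_diameter([])


class TestExpand:
    def _disk_particle(self, make_disk, radius=10):
        mask = make_disk((64, 64), (32, 32), radius)
        return analyze_particles(mask, pixel_size=1.0)[0]

    def test_factor_zero_is_identity(self, make_disk):
        p = self._disk_particle(make_disk)
        zone = expand_by_feret(p, factor=0.0, shape=(64, 64))
        np.testing.assert_array_equal(zone, p.mask((64, 64)))

    def test_zone_grows_with_factor_and_contains_particle(self, make_disk):
        p = self._disk_particle(make_disk)
        areas = []
        for f in (0.0, 0.1, 0.25, 0.5):
            zone = expand_by_feret(p, factor=f, shape=(64, 64))
            assert (zone | p.mask((64, 64))).sum() == zone.sum()  # contains particle
            areas.append(zone.sum())
        assert areas == sorted(areas) and len(set(areas)) == len(areas)

    def test_disk_expansion_matches_brute_dilation(self, make_disk):
        p = self._disk_particle(make_disk, radius=10)
        zone = expand_by_feret(p, factor=0.25, shape=(64, 64))
        radius_px = int(round(0.25 * p.feret))
        expected = dilate_disk(p.mask((64, 64)), radius_px)
        np.testing.assert_array_equal(zone, expected)
        # a disk of r=10 expanded by 0.25×Feret(≈20) is a disk of r≈15
        assert np.sqrt(zone.sum() / np.pi) == pytest.approx(15, abs=1)


class TestBackground:
    def test_constant_images_return_constant(self):
        imgs = [PlaneImage(np.full((40, 40), 12.0)) for _ in range(4)]
        assert estimate_background(imgs, box=16, subset_fraction=1.0, seed=0) == 12.0

    def test_box_avoids_bright_blob(self, rng):
        img = np.full((60, 60), 10.0)
        img[:20, :20] = 200.0  # bright corner
        level = estimate_background([PlaneImage(img)], box=20,
                                    subset_fraction=1.0, seed=0)
        assert level == pytest.approx(10.0)

    def test_single_image_minimal_box_mean_matches_exhaustive_grid(self, rng):
        img = rng.random((30, 30)) * 100
        box = 10
        level = estimate_background([PlaneImage(img)], box=box,
                                    subset_fraction=1.0, seed=0)
        # oracle: exhaustive scan over the half-box-stride grid
        positions = list(range(0, 30 - box + 1, box // 2))
        if positions[-1] != 30 - box:
            positions.append(30 - box)
        means = [img[y:y + box, x:x + box].mean() for y in positions for x in positions]
        assert level == pytest.approx(min(means))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_background([], box=10)


class TestCalls:
    def _particle(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[14:18, 14:18] = True
        return analyze_particles(mask, min_size=0.0, circ_range=(0.0, 1.0))[0]

    def test_above_background_is_positive(self):
        p = self._particle()
        chat = np.full((32, 32), 100.0)
        rec = call_positives([p], chat, background=10.0)[0]
        assert rec.positive

    def test_equal_to_background_is_negative(self):
        p = self._particle()
        chat = np.full((32, 32), 10.0)
        rec = call_positives([p], chat, background=10.0)[0]
        assert not rec.positive  # strict inequality decision

    def test_count_invariant_to_particle_order(self, rng):
        cfg = SpinalConfig(n_nuclei=12)
        isl1, chat, _ = generate_spinal_image(cfg, seed=5)
        from punctavol.mncount import (binary_cleanup, enhance_contrast,
                                       rolling_ball, yen_threshold)

        proc = rolling_ball(enhance_contrast(isl1), 30)
        parts = analyze_particles(binary_cleanup(proc.data >= yen_threshold(proc)),
                                  pixel_size=isl1.pixel_size)
        fwd = call_positives(parts, chat, background=cfg.background)
        rev = call_positives(parts[::-1], chat, background=cfg.background)
        assert sum(r.positive for r in fwd) == sum(r.positive for r in rev)


class TestNormalize:
    def test_fifty_sections_of_30um_is_1p5_mm(self):
        series = SectionSeries(n_sections=50, thickness=30.0)
        assert series.length_mm == pytest.approx(1.5)

    def test_thirty_neurons_gives_20_per_mm(self):
        series = SectionSeries(n_sections=50, thickness=30.0)
        assert normalize_per_mm(30, series) == pytest.approx(20.0)
        assert normalize_per_mm(0, series) == 0.0

    def test_linear_in_count(self):
        series = SectionSeries(n_sections=10, thickness=25.0)
        assert normalize_per_mm(8, series) == pytest.approx(2 * normalize_per_mm(4, series))

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            SectionSeries(n_sections=0, thickness=30.0)
        with pytest.raises(ValueError):
            SectionSeries(n_sections=5, thickness=0.0)


class TestEndToEnd:
    CONFIG = MotorNeuronConfig(rolling_ball_radius=30, background_box=64,
                               background_subset_fraction=1.0)

    @pytest.mark.parametrize("n_nuclei,fraction", [(10, 0.6), (20, 0.5), (15, 0.0)])
    def test_noise_free_exact_recovery(self, n_nuclei, fraction):
        cfg = SpinalConfig(n_nuclei=n_nuclei, double_positive_fraction=fraction)
        isl1, chat, truth = generate_spinal_image(cfg, seed=40 + n_nuclei)
        result = count_motor_neurons(isl1, chat, config=self.CONFIG, seed=0)
        assert result["count"] == truth.true_positive_count
        assert result["n_particles"] == n_nuclei

    def test_noisy_recovery_within_ten_percent(self):
        # σ = 10% of halo contrast; 3·sd(background) decision margin
        noisy_cfg = MotorNeuronConfig(rolling_ball_radius=30, background_box=64,
                                      background_subset_fraction=1.0,
                                      background_margin_k=3.0)
        errors = []
        for seed in range(5):
            cfg = SpinalConfig(n_nuclei=20, noise_sigma=0.1 * 120.0)
            isl1, chat, truth = generate_spinal_image(cfg, seed=300 + seed)
            result = count_motor_neurons(isl1, chat, config=noisy_cfg, seed=0)
            errors.append(abs(result["count"] - truth.true_positive_count)
                          / truth.true_positive_count)
        assert max(errors) <= 0.10
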