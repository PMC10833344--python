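"""Kinematic simulator: sampling, rendering, background, detector noise."""

import warnings

import numpy as np
import pytest

from diffraqc.condition import MASK_SENTINEL
from diffraqc.geometry import pixel_radius_map
from diffraqc.simulate import (SimulationConfig, add_background,
                               apply_detector, build_training_set,
                               count_bragg_peaks, generate_examples,
                               make_labeled_example, reflection_intensity,
                               render_spots, sample_scene)
from diffraqc.trend import b_from_resolution


@pytest.fixture(scope="module")
def base_config():
    return SimulationConfig(task="overlap")


class TestSampleScene:
    def test_degenerate_distribution_forces_single_lattice(self):
        cfg = SimulationConfig(task="overlap", lattice_probs=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(0)
        assert all(sample_scene(cfg, rng).ensemble.n_lattices == 1
                   for _ in range(50))

    def test_resolution_task_is_always_single_lattice(self):
        cfg = SimulationConfig(task="resolution")
        rng = np.random.default_rng(0)
        assert all(sample_scene(cfg, rng).ensemble.n_lattices == 1
                   for _ in range(50))

    def test_same_seed_gives_byte_identical_scene_record(self, base_config):
        s1 = sample_scene(base_config, np.random.default_rng(123))
        s2 = sample_scene(base_config, np.random.default_rng(123))
        assert s1.to_json() == s2.to_json()

    def test_sampled_values_respect_configured_ranges(self, base_config):
        rng = np.random.default_rng(5)
        for _ in range(30):
            sc = sample_scene(base_config, rng)
            assert 200.0 <= sc.geometry.distance_mm <= 300.0
            assert sc.ensemble.n_lattices in (1, 2, 3)
            assert sc.ensemble.misorientation_sigma_deg in (0.1, 1.0, 10.0)
            assert 0.01 <= sc.background_scale <= 1.25
            b = sc.ensemble.crystals[0].b_factor
            assert b_from_resolution(1.5) <= b <= b_from_resolution(4.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(lattice_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(d_range_A=(4.5, 1.5))
        with pytest.raises(ValueError):
            SimulationConfig(task="banana")


class TestRenderSpots:
    def test_debye_waller_intensity_ratio_is_exact(self):
        # two reflections of equal F^2 at d1, d2:
        # I1/I2 = exp(-(B/2)(d1^-2 - d2^-2))
        B, d1, d2 = 35.0, 1.8, 3.2
        i1 = reflection_intensity(1.0, B, d1)
        i2 = reflection_intensity(1.0, B, d2)
        expect = np.exp(-(B / 2.0) * (d1 ** -2 - d2 ** -2))
        assert i1 / i2 == pytest.approx(expect, rel=1e-12)

    def test_zero_b_has_flat_shell_means(self):
        # B = 0: mean per-spot intensity in equal-count resolution shells
        # is flat within sampling error of the exponential F^2 draws
        cfg = SimulationConfig(task="resolution")
        tables = []
        rng = np.random.default_rng(10)
        for _ in range(50):
            scene = sample_scene(cfg, rng)
            for c in scene.ensemble.crystals:
                c.b_factor = 0.0
            _, table = render_spots(scene, return_spots=True)
            tables.append(table)
        table = np.vstack(tables)
        order = np.argsort(table[:, 0])
        shells = np.array_split(table[order], 8)
        means = np.array([s[:, 1].mean() for s in shells])
        counts = np.array([len(s) for s in shells])
        # exponential F^2: sd of a shell mean is mean / sqrt(n)
        z = np.abs(means - means.mean()) / (means.mean() / np.sqrt(counts))
        assert np.all(z < 4.0)

    def test_two_lattices_roughly_double_peak_count(self):
        from diffraqc.simulate import axis_angle_rotation
        cfg = SimulationConfig(task="overlap", misorientation_sigmas_deg=(10.0,),
                               lattice_probs=(1.0, 0.0, 0.0), d_range_A=(2.8, 2.81))
        rng = np.random.default_rng(42)
        scene = sample_scene(cfg, rng)
        img1 = render_spots(scene)
        two = sample_scene(
            SimulationConfig(task="overlap", misorientation_sigmas_deg=(10.0,),
                             lattice_probs=(0.0, 1.0, 0.0), d_range_A=(2.8, 2.81)),
            np.random.default_rng(42))
        # same geometry/cell/B; second lattice misoriented by a full 10 deg
        two.geometry = scene.geometry
        u0 = scene.ensemble.crystals[0].orientation
        for c in two.ensemble.crystals:
            c.b_factor = scene.ensemble.crystals[0].b_factor
        two.ensemble.crystals[0].orientation = u0
        two.ensemble.crystals[1].orientation = axis_angle_rotation(
            np.array([1.0, 1.0, 0.0]), np.radians(10.0)) @ u0
        img2 = render_spots(two)
        n1 = count_bragg_peaks(img1, threshold=1.0)
        n2 = count_bragg_peaks(img2, threshold=1.0)
        assert n1 > 50
        assert 1.6 <= n2 / n1 <= 2.4

    def test_debye_waller_radial_decay_slope(self):
        # log of shell-averaged spot intensity vs 1/(2 d^2) has slope -B
        cfg = SimulationConfig(task="resolution", d_range_A=(2.0, 2.0001))
        rng = np.random.default_rng(3)
        xs, ys = [], []
        for _ in range(10):
            scene = sample_scene(cfg, rng)
            B = scene.ensemble.crystals[0].b_factor
            _, table = render_spots(scene, return_spots=True)
            order = np.argsort(table[:, 0])
            for shell in np.array_split(table[order], 12):
                xs.append(np.mean(1.0 / (2.0 * shell[:, 0] ** 2)))
                ys.append(np.log(shell[:, 1].mean()))
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(-B, rel=0.10)


class TestBackground:
    def test_zero_scale_leaves_image_unchanged(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(1))
        scene.background_scale = 0.0
        img = np.zeros((512, 512))
        np.testing.assert_array_equal(add_background(img, scene), img)

    def test_linearity_in_scale(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(2))
        img = np.zeros((512, 512))
        scene.background_scale = 0.4
        bg1 = add_background(img, scene)
        scene.background_scale = 0.8
        bg2 = add_background(img, scene)
        np.testing.assert_allclose(bg2, 2.0 * bg1, rtol=1e-12)

    def test_azimuthal_symmetry(self, base_config):
        # shell means vary azimuthally by < 1% of the shell mean
        scene = sample_scene(base_config, np.random.default_rng(3))
        scene.background_scale = 1.0
        bg = add_background(np.zeros((512, 512)), scene)
        r = pixel_radius_map(scene.geometry)
        shell = (r > 40) & (r < 42)
        ss, ff = np.nonzero(shell)
        ang = np.arctan2(ss - scene.geometry.beam.center_slow_px,
                         ff - scene.geometry.beam.center_fast_px)
        vals = bg[shell]
        sectors = np.digitize(ang, np.linspace(ang.min(), ang.max() + 1e-9, 9))
        sector_means = [vals[sectors == k].mean() for k in range(1, 9)]
        assert np.std(sector_means) < 0.01 * np.mean(vals)

    def test_ice_rings_add_sharp_features(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(4))
        scene.background_scale = 1.0
        base = add_background(np.zeros((512, 512)), scene)
        scene.ice_rings = True
        iced = add_background(np.zeros((512, 512)), scene)
        assert iced.max() > base.max()


class TestApplyDetector:
    def test_zero_expectation_zero_noise_gives_zeros(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(5))
        scene.read_noise = 0.0
        scene.bad_regions = []
        scene.hot_pixels = scene.hot_pixels[:0]
        out = apply_detector(np.zeros((512, 512)), scene)
        r = pixel_radius_map(scene.geometry)
        assert np.all(out[r > scene.geometry.beam.beamstop_mm] == 0)

    def test_poisson_gain_sample_mean(self, base_config):
        # constant expectation 9.5: sample mean over many draws matches
        # expectation * gain within 3 sigma
        scene = sample_scene(base_config, np.random.default_rng(6))
        scene.read_noise = 0.0
        scene.bad_regions = []
        scene.hot_pixels = scene.hot_pixels[:0]
        object.__setattr__(scene.geometry.beam, "beamstop_mm", 0.0)
        expect = 9.5
        img = np.full((512, 512), expect)
        out = apply_detector(img, scene, rng=np.random.default_rng(0))
        n = out.size
        sigma = np.sqrt(expect / n) * scene.geometry.detector.gain
        assert abs(out.mean() - expect * scene.geometry.detector.gain) < 3 * sigma

    def test_beamstop_pixels_exactly_zero(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(7))
        out = apply_detector(np.full((512, 512), 50.0), scene)
        r = pixel_radius_map(scene.geometry)
        assert np.all(out[r <= scene.geometry.beam.beamstop_mm] == 0)

    def test_masks_and_hot_pixels(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(8))
        scene.bad_regions = [(10, 20, 30, 40)]
        scene.hot_pixels = np.array([[100, 200]])
        out = apply_detector(np.zeros((512, 512)), scene)
        assert np.all(out[10:20, 30:40] == MASK_SENTINEL)
        assert out[100, 200] == scene.geometry.detector.saturation

    def test_negative_expectation_is_internal_error(self, base_config):
        scene = sample_scene(base_config, np.random.default_rng(9))
        with pytest.raises(RuntimeError):
            apply_detector(np.full((4, 4), -1.0), scene)


class TestLabeledExamples:
    def test_label_convention_2A_is_half_inverse_angstrom(self):
        # B chosen for 2 A resolution must be labeled 0.5 A^-1
        cfg = SimulationConfig(task="resolution", d_range_A=(2.0, 2.0 + 1e-12))
        ex = make_labeled_example(cfg, np.random.default_rng(0))
        assert ex.inverse_resolution == pytest.approx(0.5, abs=1e-9)
        assert ex.b_factor == pytest.approx(b_from_resolution(2.0), rel=1e-9)

    def test_overlap_label_equals_lattice_count_rule(self):
        cfg = SimulationConfig(task="overlap")
        for ex in generate_examples(cfg, 12, seed=4):
            assert ex.is_overlapped == (ex.n_lattices > 1)

    def test_fixed_seed_reproduces_pixels_and_labels(self):
        cfg = SimulationConfig(task="overlap")
        ex1 = next(generate_examples(cfg, 1, seed=99))
        ex2 = next(generate_examples(cfg, 1, seed=99))
        np.testing.assert_array_equal(ex1.pixels, ex2.pixels)
        assert ex1.inverse_resolution == ex2.inverse_resolution
        assert ex1.n_lattices == ex2.n_lattices

    def test_pixels_are_counts_with_sentinel(self):
        cfg = SimulationConfig(task="overlap")
        ex = next(generate_examples(cfg, 1, seed=5))
        assert ex.pixels.dtype == np.int32
        assert ex.pixels.min() >= MASK_SENTINEL
        assert ex.pixels.max() <= ex.scene.geometry.detector.saturation

    def test_training_set_geometry_and_shapes(self):
        cfg = SimulationConfig(task="resolution")
        ds = build_training_set(cfg, 4, seed=1)
        assert ds["images"].shape == (4, 512, 512)
        assert ds["geometry"]["p_eff_mm"][0] == pytest.approx(1.0)
        assert np.all((ds["labels"] > 0.2) & (ds["labels"] < 0.7))
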