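"""Synthetic phantom: shapes, ground truth, rasterization, rendering, raters."""

import numpy as np
import pytest

import lithoseg as ls
from lithoseg.errors import InvalidSpecError, OutOfBoundsError
from lithoseg.phantom import fibonacci_sphere


def _sphere_spec(r=5.0, density=600.0, center=(0.0, 0.0, 0.0)):
    return ls.StoneSpec("s", "sphere", {"semi_axes": (r, r, r)}, density, center)


class HalfSpace:
    """x <= x0 half-space, for the analytic boundary-occupancy check."""

    def __init__(self, x0, center, radius):
        self.x0 = x0
        self.center = np.asarray(center, float)
        self.bounding_radius_mm = radius

    def contains(self, pts):
        return np.asarray(pts)[..., 0] <= self.x0


class TestStoneShapes:
    def test_sphere_ground_truth_closed_form(self):
        _, truth = ls.make_stone_shape(_sphere_spec(5.0))
        assert truth.volume_ml == pytest.approx(0.5236, abs=1e-4)
        assert truth.diameter_mm == pytest.approx(10.0)

    def test_ellipsoid_ground_truth_closed_form(self):
        spec = ls.StoneSpec("e", "ellipsoid", {"semi_axes": (5, 3, 2)}, 600)
        _, truth = ls.make_stone_shape(spec)
        assert truth.volume_ml == pytest.approx(0.1257, abs=1e-4)
        assert truth.diameter_mm == pytest.approx(10.0)

    def test_perturbed_volume_matches_fine_rasterization(self):
        rng = np.random.default_rng(42)
        coeffs = rng.normal(size=5)
        coeffs /= np.abs(coeffs).sum()
        spec = ls.StoneSpec(
            "p",
            "perturbed_ellipsoid",
            {"semi_axes": (6.0, 4.5, 3.5), "amplitude": 0.15, "coeffs": tuple(coeffs)},
            600,
            (12.0, 12.0, 12.0),
        )
        shape, truth = ls.make_stone_shape(spec)
        # independent oracle: brute rasterization at doubled (16x) supersampling
        fine = ls.rasterize_partial_volume(
            shape, (35, 35, 35), np.full(3, 0.7), np.zeros(3), supersample=16
        )
        vol_raster = fine.sum() * 0.7**3 / 1000.0
        assert truth.volume_ml == pytest.approx(vol_raster, rel=0.01)

    def test_perturbed_diameter_at_least_sphere_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            coeffs = rng.normal(size=5)
            coeffs /= np.abs(coeffs).sum()
            spec = ls.StoneSpec(
                "p",
                "perturbed_ellipsoid",
                {"semi_axes": (5.0, 4.0, 3.0), "amplitude": 0.1, "coeffs": tuple(coeffs)},
                900,
            )
            _, truth = ls.make_stone_shape(spec)  # GroundTruth validates the bound
            assert truth.diameter_mm > 0

    def test_unknown_family_rejected(self):
        with pytest.raises(InvalidSpecError):
            ls.StoneSpec("x", "cube", {"semi_axes": (5, 5, 5)}, 600)

    def test_minimum_diameter_inclusion_rule(self):
        with pytest.raises(InvalidSpecError):
            ls.StoneSpec("x", "ellipsoid", {"semi_axes": (5.0, 3.0, 1.5)}, 600)

    def test_low_density_rejected(self):
        with pytest.raises(InvalidSpecError):
            _sphere_spec(density=50.0)


class TestRasterization:
    def test_halfspace_boundary_voxels_half(self):
        hs = HalfSpace(x0=7.0, center=(7.0, 7.0, 7.0), radius=6.0)
        occ = ls.rasterize_partial_volume(hs, (21, 21, 21), np.ones(3), np.zeros(3), 8)
        assert np.all(occ[7, 2:12, 2:12] == 0.5)
        assert np.all(occ[5, 2:12, 2:12] == 1.0)
        assert np.all(occ[9, 2:12, 2:12] == 0.0)

    def test_supersample_one_is_binary_center_test(self):
        shape = ls.StoneShape(np.full(3, 10.5), np.full(3, 5.0))
        occ = ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), 1)
        assert set(np.unique(occ)) <= {0.0, 1.0}

    def test_sphere_occupancy_volume_within_half_percent(self):
        shape = ls.StoneShape(np.full(3, 10.5), np.full(3, 5.0))
        occ = ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), 8)
        vol = occ.sum() * 0.7**3
        assert vol == pytest.approx(523.5988, rel=0.005)
        assert occ.max() == 1.0 and occ.min() == 0.0

    def test_supersample_error_decreases_monotonically(self):
        shape = ls.StoneShape(np.full(3, 10.5), np.full(3, 5.0))
        analytic = 4 / 3 * np.pi * 125.0
        errors = []
        for s in (1, 2, 4, 8):
            occ = ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), s)
            errors.append(abs(occ.sum() * 0.7**3 - analytic))
        assert errors == sorted(errors, reverse=True)

    def test_shell_classification_matches_full_supersampling(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            coeffs = rng.normal(size=5)
            coeffs /= np.abs(coeffs).sum()
            shape = ls.StoneShape(
                np.full(3, 12.0), np.array([6.0, 4.5, 3.5]), float(rng.uniform(0.05, 0.2)), coeffs
            )
            fast = ls.rasterize_partial_volume(shape, (35, 35, 35), np.full(3, 0.7), np.zeros(3), 4)

            class Naive:
                center = shape.center
                bounding_radius_mm = shape.bounding_radius_mm

                def contains(self, p, s=shape):
                    return s.contains(p)

            slow = ls.rasterize_partial_volume(Naive(), (35, 35, 35), np.full(3, 0.7), np.zeros(3), 4)
            np.testing.assert_array_equal(fast, slow)

    def test_out_of_bounds_shape_rejected(self):
        shape = ls.StoneShape(np.full(3, 2.0), np.full(3, 5.0))
        with pytest.raises(OutOfBoundsError):
            ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), 2)


class TestRendering:
    def test_noop_physics_interior_exact(self):
        cfg = ls.PhantomConfig(psf_sigma_mm=0.0, noise_sd_hu=0.0)
        occ = np.zeros((9, 9, 9))
        occ[3:6, 3:6, 3:6] = 1.0
        vol = ls.render_ct(occ, cfg, 600.0)
        assert np.all(vol.values[3:6, 3:6, 3:6] == 600.0)
        assert np.all(vol.values[0] == 0.0)

    def test_blur_conserves_total_hu(self):
        cfg = ls.PhantomConfig(psf_sigma_mm=0.5, noise_sd_hu=0.0)
        occ = np.zeros((41, 41, 41))
        occ[17:24, 17:24, 17:24] = 1.0  # well padded: truncation negligible
        vol = ls.render_ct(occ, cfg, 600.0)
        assert vol.values.sum() == pytest.approx(occ.sum() * 600.0, rel=1e-9)

    def test_same_seed_bit_identical(self):
        cfg = ls.PhantomConfig(seed=5)
        occ = np.zeros((15, 15, 15))
        occ[5:9, 5:9, 5:9] = 1.0
        a = ls.render_ct(occ, cfg, 800.0)
        b = ls.render_ct(occ, cfg, 800.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_hu_bounded_by_density_plus_noise(self, small_phantom):
        cfg = small_phantom.config
        hi = max(s.density_hu for s in small_phantom.specs)
        assert small_phantom.volume.values.max() <= hi + 5 * cfg.noise_sd_hu
        assert small_phantom.volume.values.min() >= cfg.background_hu - 5 * cfg.noise_sd_hu

    def test_half_maximum_isolevel_volume_near_truth(self):
        # psf=0, noise=0: thresholding the mixture at half its density must
        # recover the truth to within one surface-shell volume
        cfg = ls.PhantomConfig(psf_sigma_mm=0.0, noise_sd_hu=0.0)
        shape = ls.StoneShape(np.full(3, 10.5), np.full(3, 5.0))
        occ = ls.rasterize_partial_volume(shape, (31, 31, 31), np.full(3, 0.7), np.zeros(3), 8)
        vol = ls.render_ct(occ, cfg, 600.0)
        mask = vol.values >= 300.0
        _, n_surf = ls.surface_voxels(mask)
        voxvol = 0.7**3
        assert abs(mask.sum() * voxvol - 523.5988) <= n_surf * voxvol


class TestRaters:
    def test_zero_cv_reproduces_truth(self, rng):
        truth = ls.GroundTruth("s", 0.5236, 10.001)
        rec = ls.simulate_raters(truth, 0.0, rng)
        assert rec.volumes_ml == (0.5236,) * 3
        assert rec.reference_volume_ml == 0.5236
        assert rec.reference_diameter_mm == 10.001

    def test_reference_unbiased_over_many_stones(self):
        rng = np.random.default_rng(99)
        truth = ls.GroundTruth("s", 1.0, 12.5)
        rel = [
            ls.simulate_raters(truth, 0.05, rng).reference_volume_ml - 1.0 for _ in range(1000)
        ]
        # SE of the mean of 1000 3-rater means at cv=0.05 is ~0.0009
        assert abs(np.mean(rel)) < 4 * 0.05 / np.sqrt(3 * 1000)

    def test_fixed_seed_reproducible(self):
        truth = ls.GroundTruth("s", 0.3, 8.5)
        a = ls.simulate_raters(truth, 0.03, np.random.default_rng(4))
        b = ls.simulate_raters(truth, 0.03, np.random.default_rng(4))
        assert a == b


class TestMakePhantom:
    def test_counts_preserved(self, small_phantom):
        assert len(small_phantom.annotations) == 12
        assert len(small_phantom.truths) == 12
        assert len(small_phantom.raters) == 12
        ids = {a.stone_id for a in small_phantom.annotations}
        assert ids == {t.stone_id for t in small_phantom.truths}

    def test_annotation_sphere_contains_stone_surface(self, small_phantom):
        for spec, ann in zip(small_phantom.specs, small_phantom.annotations):
            shape, _ = ls.make_stone_shape(spec)
            pts = shape.surface_points(1024)
            d = np.linalg.norm(pts - np.asarray(ann.center_mm), axis=1)
            assert d.max() <= ann.radius_mm

    def test_annotation_spheres_disjoint(self, small_phantom):
        anns = small_phantom.annotations
        for i, a in enumerate(anns):
            for b in anns[i + 1 :]:
                d = np.linalg.norm(np.asarray(a.center_mm) - np.asarray(b.center_mm))
                assert d > a.radius_mm + b.radius_mm

    def test_same_seed_identical_ground_truth(self):
        a = ls.make_phantom(5, ls.PhantomConfig(seed=21))
        b = ls.make_phantom(5, ls.PhantomConfig(seed=21))
        assert a.truths == b.truths
        assert a.raters == b.raters
        np.testing.assert_array_equal(a.volume.values, b.volume.values)

    def test_fibonacci_directions_unit_norm(self):
        u = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(u, axis=1), 1.0, atol=1e-12)
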