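"""Per-grain trait operators against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earset.errors import CalibrationError
from earset.traits import (
    CalibrationModel,
    apply_sieve,
    aspect_ratio,
    compute_all_traits,
    fit_calibration,
    min_covering_sphere,
    min_diameter,
    surface_voxel_count,
    traits_frame,
    uncalibrated_mass_index,
)
from earset.volume import Volume

from conftest import region_from_mask
from _oracles import (
    brute_force_min_sphere,
    brute_force_surface_count,
    dense_direction_min_width,
    rasterize_ellipsoid,
)


class TestMinCoveringSphere:
    def test_single_point(self):
        c, r = min_covering_sphere(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(c, [1, 2, 3]) and r == 0.0

    def test_two_points_midpoint(self):
        c, r = min_covering_sphere(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert np.allclose(c, [1, 0, 0]) and r == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            min_covering_sphere(np.empty((0, 3)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=2, max_value=12))
    def test_matches_exhaustive_support_oracle(self, seed, n):
        """Exact agreement with the brute-force support-subset oracle."""
        pts = np.random.default_rng(seed).uniform(-10, 10, size=(n, 3))
        _, r = min_covering_sphere(pts)
        _, r_oracle = brute_force_min_sphere(pts)
        assert r == pytest.approx(r_oracle, abs=1e-9)

    def test_large_cospherical_set(self):
        """Hull pre-reduction and violator refinement stay exact on a
        densely sampled sphere surface."""
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((5000, 3))
        pts = 7.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        _, r = min_covering_sphere(pts)
        assert r == pytest.approx(7.0, rel=1e-6)


class TestAspectRatio:
    def test_single_voxel_is_sphere_like(self):
        assert aspect_ratio(np.array([[3, 4, 5]]), 0.1) == 1.0

    def test_digitized_sphere_close_to_one(self):
        coords = np.argwhere(rasterize_ellipsoid((20, 20, 20)))
        assert aspect_ratio(coords, 1.0) >= 0.95

    def test_thin_rod_closed_form(self):
        """1x1x200 rod: r_eq = (3*200/4pi)^(1/3), r_mcs = 199/2."""
        rod = np.stack([np.zeros(200), np.zeros(200), np.arange(200)], axis=1).astype(int)
        expected = (3 * 200 / (4 * np.pi)) ** (1 / 3) / (199 / 2)
        ratio = aspect_ratio(rod, 1.0)
        assert ratio == pytest.approx(expected, rel=1e-6)
        assert ratio == pytest.approx(0.036, abs=0.001)


class TestSurface:
    def test_single_voxel(self):
        assert surface_voxel_count(np.ones((1, 1, 1), dtype=bool)) == 1

    def test_cube_all_but_centre(self):
        assert surface_voxel_count(np.ones((3, 3, 3), dtype=bool)) == 26

    def test_digitized_sphere_matches_brute_force(self):
        mask = rasterize_ellipsoid((10, 10, 10))
        assert surface_voxel_count(mask) == brute_force_surface_count(mask)

    def test_sphere_smoother_than_plane(self):
        """Relative surface is lower for a ball than for a one-voxel plane
        of comparable voxel count."""
        sphere = rasterize_ellipsoid((10, 10, 10))
        n = sphere.sum()
        side = int(np.ceil(np.sqrt(n)))
        plane = np.ones((1, side, side), dtype=bool)
        s_ratio = surface_voxel_count(sphere) / sphere.sum()
        p_ratio = surface_voxel_count(plane) / plane.sum()
        assert s_ratio < p_ratio


class TestMinDiameter:
    def test_sphere_above_sieve(self):
        coords = np.argwhere(rasterize_ellipsoid((12.5, 12.5, 12.5)))
        assert min_diameter(coords, 0.1) >= 2.4

    def test_small_sphere_below_sieve(self):
        coords = np.argwhere(rasterize_ellipsoid((7.5, 7.5, 7.5)))
        assert min_diameter(coords, 0.1) < 2.0

    def test_flat_ellipsoid_matches_dense_oracle(self):
        """(3, 1.5, 0.8) mm ellipsoid: minimal width ~1.6 mm within 5%."""
        coords = np.argwhere(rasterize_ellipsoid((30, 15, 8)))
        width = min_diameter(coords, 0.1)
        assert width == pytest.approx(1.6, rel=0.05)
        assert width == pytest.approx(dense_direction_min_width(coords, 0.1), rel=0.03)

    def test_rotation_invariance(self):
        """Aspect ratio and min width vary < 3% under random rotations."""
        rng = np.random.default_rng(5)
        widths, aspects = [], []
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            Q, _ = np.linalg.qr(A)
            coords = np.argwhere(rasterize_ellipsoid((22, 14, 10), rotation=Q))
            widths.append(min_diameter(coords, 0.1))
            aspects.append(aspect_ratio(coords, 0.1))
        assert np.ptp(widths) / np.mean(widths) < 0.03
        assert np.ptp(aspects) / np.mean(aspects) < 0.03


class TestSieve:
    def _seed(self, d):
        from earset.traits import SeedTraits

        return SeedTraits(
            ear_id="e",
            seed_label=1,
            voxel_count=100,
            volume_mm3=0.1,
            virtual_weight_g=0.01,
            centre_of_mass_mm=np.zeros(3),
            mean_attenuation=0.8,
            aspect_ratio=0.5,
            surface_voxels=50,
            surface_to_volume=0.5,
            min_diameter_mm=d,
            passes_sieve=d >= 2,
            mass_index=0.08,
        )

    def test_partition_is_exhaustive(self):
        seeds = [self._seed(d) for d in (0.5, 1.9, 2.0, 2.5, 3.0)]
        retained, omitted = apply_sieve(seeds)
        assert len(retained) + len(omitted) == len(seeds)
        assert [s.min_diameter_mm for s in retained] == [2.0, 2.5, 3.0]

    def test_zero_cutoff_retains_everything(self):
        seeds = [self._seed(d) for d in (0.5, 3.0)]
        retained, omitted = apply_sieve(seeds, cutoff_mm=0.0)
        assert len(retained) == 2 and omitted == []


class TestMassIndex:
    def _volume_with(self, grey):
        return Volume(grey, voxel_size_um=1000.0, grey_per_absorption=75000.0)

    def test_homogeneous_region(self):
        """V = 10 mm^3 at absorption 0.8 gives mass index 8.0."""
        grey = np.zeros((1, 2, 5), dtype=np.uint16)
        grey[0] = int(0.8 * 75000)
        vol = self._volume_with(grey)
        coords = np.argwhere(grey > 0)
        index, com, mean_att = uncalibrated_mass_index(coords, vol)
        assert index == pytest.approx(8.0, rel=1e-4)
        assert mean_att == pytest.approx(0.8, rel=1e-4)

    def test_centre_of_mass_weighting(self):
        """Absorptions 0.2 and 0.6: com sits 0.75 of the way to the denser."""
        grey = np.zeros((1, 1, 2), dtype=np.uint16)
        grey[0, 0, 0] = int(0.2 * 75000)
        grey[0, 0, 1] = int(0.6 * 75000)
        vol = self._volume_with(grey)
        _, com, _ = uncalibrated_mass_index(np.array([[0, 0, 0], [0, 0, 1]]), vol)
        frac = (com[2] - 0.5) / 1.0  # world positions 0.5 and 1.5 mm
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_missing_scale_rejected(self):
        class Bare:
            grey_per_absorption = 0.0

        with pytest.raises(ValueError, match="scale"):
            uncalibrated_mass_index(np.array([[0, 0, 0]]), Bare())

    def test_cavity_reduces_mass_index(self):
        solid = rasterize_ellipsoid((10, 8, 6))
        carved = solid.copy()
        carved[8:13, 6:11, 4:9] = False
        grey = np.where(solid, 60000, 0).astype(np.uint16)
        vol = Volume(grey, voxel_size_um=100.0, grey_per_absorption=75000.0)
        i_solid, _, _ = uncalibrated_mass_index(np.argwhere(solid), vol)
        i_carved, _, _ = uncalibrated_mass_index(np.argwhere(carved), vol)
        assert i_carved < i_solid


class TestCalibration:
    def test_exact_factor(self):
        v = np.array([1.0, 2.0, 3.0])
        model = fit_calibration(v, 2 * v)
        assert model.factor_k == pytest.approx(2.0)
        assert model.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovery_under_multiplicative_noise(self):
        """5% noise, n=30: k recovered within 2% (fixed seed)."""
        rng = np.random.default_rng(123)
        v = rng.uniform(5, 50, size=30)
        k_true = 0.05
        a = k_true * v * (1 + 0.05 * rng.standard_normal(30))
        model = fit_calibration(v, a)
        assert model.factor_k == pytest.approx(k_true, rel=0.02)

    def test_unbiasedness_at_n100(self):
        """Monte-Carlo mean of k-hat matches k within the MC error."""
        rng = np.random.default_rng(7)
        k_true = 0.0016
        estimates = []
        for _ in range(200):
            v = rng.uniform(10, 100, size=100)
            a = k_true * v * (1 + 0.05 * rng.standard_normal(100))
            estimates.append(fit_calibration(v, a).factor_k)
        mc_err = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - k_true) < 4 * mc_err + 1e-12

    def test_single_pair_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0], [2.0])

    def test_nonpositive_virtual_rejected(self):
        with pytest.raises(CalibrationError):
            fit_calibration([1.0, 0.0], [2.0, 1.0])


class TestComputeAllTraits:
    def test_empty_input_gives_header_only_table(self):
        vol = Volume(np.zeros((4, 4, 4), dtype=np.uint16), 100.0, 75000.0)
        frame = traits_frame(compute_all_traits([], vol))
        assert len(frame) == 0
        assert list(frame.columns)[:3] == ["ear_id", "seed_label", "voxel_count"]

    def test_single_voxel_degenerate_contract(self):
        grey = np.zeros((3, 3, 3), dtype=np.uint16)
        grey[1, 1, 1] = 60000
        vol = Volume(grey, 100.0, 75000.0)
        region = region_from_mask(grey > 0)
        params_floor_1 = compute_all_traits([region], vol)
        (row,) = params_floor_1
        assert row.aspect_ratio == 1.0
        assert row.surface_voxels == 1
        assert row.voxel_count == 1

    def test_invariants_on_phantom_regions(self, small_ear):
        from earset.segment import segment_seeds, separate_ears

        spec, volume, truth = small_ear
        ear = separate_ears(volume, 1)[0]
        seeds = compute_all_traits(segment_seeds(ear), ear.volume, None, "ear0")
        for s in seeds:
            assert s.volume_mm3 == pytest.approx(s.voxel_count * ear.volume.voxel_volume_mm3)
            assert 0 < s.aspect_ratio <= 1
            assert 1 <= s.surface_voxels <= s.voxel_count
            assert s.virtual_weight_g > 0

    def test_carving_monotonicity(self):
        """Removing voxels never increases count or mass index."""
        rng = np.random.default_rng(11)
        mask = rasterize_ellipsoid((8, 6, 5))
        grey = np.where(mask, 60000, 0).astype(np.uint16)
        vol = Volume(grey, 100.0, 75000.0)
        coords = np.argwhere(mask)
        prev_index, _, _ = uncalibrated_mass_index(coords, vol)
        for _ in range(5):
            coords = np.delete(coords, rng.integers(len(coords)), axis=0)
            index, _, _ = uncalibrated_mass_index(coords, vol)
            assert index <= prev_index
            prev_index = index
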