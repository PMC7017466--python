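"""Seed ordering along the ear, weight profiles and evaluation statistics."""

import numpy as np
import pandas as pd
import pytest

from earset.earprofile import (
    build_ear_record,
    evaluate_against_actual,
    group_summary,
    order_and_normalize,
    weight_position_profile,
)
from earset.traits import SeedTraits


def make_seed(z, weight=0.03, d=2.5, label=1):
    return SeedTraits(
        ear_id="e0",
        seed_label=label,
        voxel_count=1000,
        volume_mm3=1.0,
        virtual_weight_g=weight,
        centre_of_mass_mm=np.array([z, 0.0, 0.0]),
        mean_attenuation=0.8,
        aspect_ratio=0.5,
        surface_voxels=100,
        surface_to_volume=0.1,
        min_diameter_mm=d,
        passes_sieve=d >= 2.0,
        mass_index=weight,
    )


AXIS = (np.zeros(3), np.array([1.0, 0.0, 0.0]))


class TestOrdering:
    def test_three_seeds_normalize_to_unit_interval(self):
        seeds = [make_seed(z) for z in (5.0, 0.0, 10.0)]
        ordered = order_and_normalize(seeds, *AXIS)
        assert [s.axial_position_norm for s in ordered] == [0.0, 0.5, 1.0]
        assert [s.axial_position_mm for s in ordered] == [0.0, 5.0, 10.0]

    def test_axis_sign_does_not_flip_bottom(self):
        """The bottom seed is position 0 even for a downward axis vector."""
        seeds = [make_seed(z) for z in (0.0, 10.0)]
        down = order_and_normalize(seeds, np.zeros(3), np.array([-1.0, 0, 0]))
        assert down[0].centre_of_mass_mm[0] == 0.0
        assert down[0].axial_position_norm == 0.0

    def test_single_seed_at_zero(self):
        (only,) = order_and_normalize([make_seed(4.0)], *AXIS)
        assert only.axial_position_norm == 0.0

    def test_idempotent(self):
        seeds = [make_seed(z) for z in (3.0, 1.0, 2.0)]
        once = order_and_normalize(seeds, *AXIS)
        twice = order_and_normalize(once, *AXIS)
        assert [s.axial_position_norm for s in once] == [s.axial_position_norm for s in twice]

    def test_matches_phantom_truth_order(self, small_ear):
        from earset.segment import segment_seeds, separate_ears
        from earset.traits import compute_all_traits

        spec, volume, truth = small_ear
        ear = separate_ears(volume, 1)[0]
        seeds = compute_all_traits(segment_seeds(ear), ear.volume)
        ordered = order_and_normalize(seeds, ear.axis_origin_mm, ear.axis_direction)
        truth_order = sorted(truth.seeds, key=lambda s: s.axial_position_mm)
        got = [s.centre_of_mass_mm[0] + ear.origin_index[0] * volume.voxel_size_mm for s in ordered]
        expect = [s.centre_mm[0] for s in truth_order]
        assert np.allclose(got, expect, atol=0.5)


class TestProfile:
    def _records(self, weights_by_pos):
        seeds = [make_seed(z, weight=w) for z, w in weights_by_pos]
        return [build_ear_record("e0", seeds, *AXIS)]

    def test_flat_weights_give_flat_profile(self):
        records = self._records([(z, 0.02) for z in np.linspace(0, 10, 21)])
        profile = weight_position_profile(records, n_bins=5)
        assert np.allclose(profile["mean_seed_weight_g"].dropna(), 0.02)

    def test_central_heavy_profile_peaks_centrally(self):
        """Mid-ear seeds twice as heavy: profile maximum in central bins,
        minimum at the extremes."""
        pos = np.linspace(0, 10, 30)
        weights = np.where((pos > 3) & (pos < 7), 0.04, 0.02)
        records = self._records(list(zip(pos, weights)))
        profile = weight_position_profile(records, n_bins=10)
        means = profile["mean_seed_weight_g"].values
        assert np.nanargmax(means) in range(3, 7)
        assert means[0] == pytest.approx(0.02) and means[-1] == pytest.approx(0.02)

    def test_mass_conservation_over_bins(self):
        """Sum over bins of mean*count equals the pooled seed weight sum."""
        rng = np.random.default_rng(2)
        records = self._records([(z, w) for z, w in zip(rng.uniform(0, 10, 40), rng.uniform(0.01, 0.05, 40))])
        profile = weight_position_profile(records, n_bins=7)
        total = np.nansum(profile["mean_seed_weight_g"] * profile["n_seeds"])
        assert total == pytest.approx(sum(s.virtual_weight_g for s in records[0].seeds), rel=1e-12)

    def test_single_seed_occupies_one_bin(self):
        profile = weight_position_profile(self._records([(5.0, 0.03)]), n_bins=4)
        assert (profile["n_seeds"] > 0).sum() == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            weight_position_profile(self._records([(5.0, 0.03)]), n_bins=1)

    def test_empty_bins_are_missing_not_zero(self):
        profile = weight_position_profile(self._records([(0.0, 0.03), (10.0, 0.05)]), n_bins=5)
        middle = profile["mean_seed_weight_g"].iloc[1:4]
        assert middle.isna().all()


def _records_with_totals(weights):
    records = []
    for i, w in enumerate(weights):
        seeds = [make_seed(z, weight=w / 3) for z in (0.0, 5.0, 10.0)]
        records.append(build_ear_record(f"e{i}", seeds, *AXIS))
    return records


class TestEvaluation:
    def test_perfect_agreement_gives_r2_one(self):
        records = []
        for i, w in enumerate([0.3, 0.6, 0.9, 1.2]):
            seeds = [make_seed(z, weight=w) for z in np.linspace(0, 10, i + 2)]
            records.append(build_ear_record(f"e{i}", seeds, *AXIS))
        actual = pd.DataFrame(
            {
                "ear_id": [r.ear_id for r in records],
                "actual_weight_g": [r.total_virtual_weight_g for r in records],
                "actual_count": [r.n_seeds_sieved for r in records],
            }
        )
        report = evaluate_against_actual(records, actual)
        assert report.r2_weight == pytest.approx(1.0)
        assert report.r2_count == pytest.approx(1.0)

    def test_r2_invariant_under_affine_actuals(self):
        rng = np.random.default_rng(3)
        records = _records_with_totals(rng.uniform(0.2, 2.0, 20))
        base = np.array([r.total_virtual_weight_g for r in records]) + rng.normal(0, 0.1, 20)
        reports = []
        for a, b in ((1.0, 0.0), (3.5, 1.2)):
            actual = pd.DataFrame(
                {"ear_id": [r.ear_id for r in records], "actual_weight_g": a * base + b}
            )
            reports.append(evaluate_against_actual(records, actual).r2_weight)
        assert reports[0] == pytest.approx(reports[1], rel=1e-9)

    def test_noise_calibrated_r2_near_population_value(self):
        """actual = virtual + noise sized for population r^2 = 0.9."""
        rng = np.random.default_rng(42)
        virtual = rng.uniform(0.2, 2.0, 100)
        sigma = np.std(virtual) / 3.0  # var ratio 9:1 -> r^2 = 0.9
        records = _records_with_totals(virtual)
        actual = pd.DataFrame(
            {
                "ear_id": [r.ear_id for r in records],
                "actual_weight_g": np.array([r.total_virtual_weight_g for r in records])
                + rng.normal(0, sigma, 100),
            }
        )
        report = evaluate_against_actual(records, actual)
        assert report.r2_weight == pytest.approx(0.9, abs=0.05)

    def test_disjoint_ids_rejected(self):
        records = _records_with_totals([0.3, 0.6])
        actual = pd.DataFrame({"ear_id": ["x", "y"], "actual_weight_g": [1.0, 2.0]})
        with pytest.raises(ValueError, match="matched"):
            evaluate_against_actual(records, actual)

    def test_constant_actual_reports_missing_r2(self):
        records = _records_with_totals([0.3, 0.6, 0.9])
        actual = pd.DataFrame(
            {"ear_id": [r.ear_id for r in records], "actual_weight_g": [1.0, 1.0, 1.0]}
        )
        assert evaluate_against_actual(records, actual).r2_weight is None


class TestEarRecord:
    def test_totals_and_counts_are_consistent(self):
        seeds = [make_seed(z, d=d) for z, (d,) in zip((0, 2, 4, 6), [(2.5,), (1.5,), (3.0,), (1.0,)])]
        record = build_ear_record("e0", seeds, *AXIS)
        assert record.n_seeds_sieved + record.n_seeds_small == 4
        assert record.n_seeds_small == 2
        assert record.total_virtual_weight_g == pytest.approx(sum(s.virtual_weight_g for s in seeds))
        assert record.ear_length_seed_span_mm == pytest.approx(6.0)


class TestGroupSummary:
    def test_single_ear_group_mean_equals_ear_mean(self):
        seeds = [make_seed(z, weight=w) for z, w in ((0, 0.02), (5, 0.04))]
        record = build_ear_record("e0", seeds, *AXIS, group="D")
        summary = group_summary([record])
        assert summary.loc["D", ("single_seed_weight_g", "mean")] == pytest.approx(0.03)
        assert summary.loc["D", ("seed_count", "mean")] == 2

    def test_group_ordering_recovered(self):
        """Groups constructed with distinct volumes keep their ordering."""
        records = []
        for g, vol_scale in (("D", 2.0), ("DH", 1.0)):
            for i in range(3):
                seeds = [make_seed(z) for z in (0, 5)]
                for s in seeds:
                    s.volume_mm3 = vol_scale
                records.append(build_ear_record(f"{g}{i}", seeds, *AXIS, group=g))
        summary = group_summary(records)
        assert (
            summary.loc["D", ("seed_volume_mm3", "mean")]
            > summary.loc["DH", ("seed_volume_mm3", "mean")]
        )

    def test_unlabelled_ears_excluded(self):
        labelled = build_ear_record("a", [make_seed(0)], *AXIS, group="D")
        unlabelled = build_ear_record("b", [make_seed(0)], *AXIS)
        summary = group_summary([labelled, unlabelled])
        assert summary.loc["D", ("seed_count", "count")] == 1
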