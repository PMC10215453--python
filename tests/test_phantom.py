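"""Synthetic phantom: determinism, ground truth, rendering invariants."""

import numpy as np
import pytest

from etquant.densitometry import DEFAULT_RANGES
from etquant.phantom import (
    PhantomSpec,
    compute_ground_truth,
    dilation_factor_for_air_increase,
    generate_phantom,
    load_ground_truth,
    true_air_increase_percent,
    write_ground_truth,
    write_phantom_series,
)
from etquant.volume import read_dicom_series


class TestSpecValidation:
    def test_rejects_dilation_below_one(self):
        with pytest.raises(ValueError):
            PhantomSpec(dilation_factor=0.9)

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError):
            PhantomSpec(lumen_width_pre_mm=(3.0, 0.0, 2.0))

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)

    def test_rejects_zero_supersampling(self):
        with pytest.raises(ValueError):
            PhantomSpec(partial_volume=0)

    def test_lumen_exceeding_volume_rejected(self):
        # axis shifted so the tube runs out of the volume's posterior face
        with pytest.raises(ValueError, match="exceeds volume bounds"):
            compute_ground_truth(PhantomSpec(axis_origin_mm=(8.0, 45.0, 9.0)))

    def test_incompatible_balloon_geometry_rejected(self):
        # a lumen this long leaves no cylindrical balloon segment
        with pytest.raises(ValueError, match="cylindrical segment"):
            compute_ground_truth(PhantomSpec(lumen_length_mm=200.0))

    def test_markers_lie_on_balloon(self):
        spec = PhantomSpec()
        tip = spec.lumen_length_mm
        start = tip - spec.balloon.length_mm
        t_a, t_b = spec.marker_ts()
        assert start <= t_a < t_b <= tip


class TestGroundTruth:
    def test_counts_equal_mask_cardinalities(self, clean_phantom):
        *_, gt = clean_phantom
        assert gt.air_count_pre == int(gt.lumen_mask_pre.sum())
        assert gt.air_count_post == int(gt.lumen_mask_post.sum())

    def test_dilation_factor_one_leaves_counts_unchanged(self):
        gt = compute_ground_truth(PhantomSpec(dilation_factor=1.0))
        assert gt.air_count_pre == gt.air_count_post
        assert np.array_equal(gt.lumen_mask_pre, gt.lumen_mask_post)

    def test_width_parameter_pass_through(self):
        spec = PhantomSpec(dilation_factor=2.0, lumen_width_pre_mm=(3.5, 2.0, 2.0))
        gt = compute_ground_truth(spec)
        assert gt.widths_post_mm[1] == pytest.approx(4.0)

    def test_post_count_monotone_in_dilation_factor(self):
        counts = [
            compute_ground_truth(PhantomSpec(dilation_factor=f)).air_count_post
            for f in (1.0, 1.3, 1.6, 2.0)
        ]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_distances_follow_cartilaginous_fraction(self):
        # 25 mm lumen at 0.3125 mm/px = 80 px; fraction 0.6 -> 48 + 32
        gt = compute_ground_truth(PhantomSpec())
        assert gt.distances_px == pytest.approx((80.0, 48.0, 32.0))

    def test_landmarks_plane_contains_lumen_axis(self):
        spec = PhantomSpec()
        gt = compute_ground_truth(spec)
        pts = [np.asarray(p) * spec.spacing for p in gt.landmarks.plane_points()]
        normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        normal /= np.linalg.norm(normal)
        for t in (0.0, 12.0, spec.lumen_length_mm):
            d = abs((spec.axis_point(t) - pts[0]) @ normal)
            assert d < 1e-9

    def test_round_trip_serialization(self, clean_phantom, tmp_path):
        *_, gt = clean_phantom
        write_ground_truth(gt, tmp_path / "gt")
        back = load_ground_truth(tmp_path / "gt")
        assert back.air_count_pre == gt.air_count_pre
        assert np.array_equal(back.lumen_mask_post, gt.lumen_mask_post)
        assert back.distances_px == pytest.approx(gt.distances_px)
        assert back.landmarks.torus_tip == pytest.approx(gt.landmarks.torus_tip)


class TestRendering:
    def test_fixed_seed_is_bit_reproducible(self):
        spec = PhantomSpec(seed=5)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        for va, vb in zip(a[:3], b[:3]):
            assert np.array_equal(va.voxels, vb.voxels)

    def test_different_seeds_differ(self):
        a = generate_phantom(PhantomSpec(seed=5))
        b = generate_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a[0].voxels, b[0].voxels)

    def test_noiseless_rendering_hits_configured_means(self, clean_spec, clean_phantom):
        pre, _during, post, gt = clean_phantom
        inten = clean_spec.intensities
        assert np.all(pre.voxels[gt.lumen_mask_pre] == inten.air)
        assert np.all(post.voxels[gt.lumen_mask_post] == inten.air)
        assert np.all(pre.voxels[gt.bone_mask] == inten.bone)
        # with no noise and no partial volume every voxel is a pure material
        assert set(np.unique(pre.voxels)) <= {inten.air, inten.tissue, inten.bone}

    def test_during_state_contains_balloon_and_markers(self, clean_spec, clean_phantom):
        _pre, during, _post, _gt = clean_phantom
        inten = clean_spec.intensities
        values = set(np.unique(during.voxels))
        assert inten.balloon in values
        assert inten.marker in values

    def test_partial_volume_produces_intermediate_tail(self):
        spec = PhantomSpec(seed=7, noise_sd=0.0, partial_volume=3)
        pre, *_ = generate_phantom(spec)
        inten = spec.intensities
        # boundary voxels average air with tissue: values strictly between
        mixed = (pre.voxels > inten.air) & (pre.voxels < inten.tissue)
        assert mixed.sum() > 0

    def test_configured_intensities_inside_reference_ranges(self):
        inten = PhantomSpec().intensities
        assert DEFAULT_RANGES.air_strict[0] <= inten.air <= DEFAULT_RANGES.air_strict[1]
        assert DEFAULT_RANGES.tissue[0] <= inten.tissue <= DEFAULT_RANGES.tissue[1]
        assert DEFAULT_RANGES.bone[0] <= inten.bone <= DEFAULT_RANGES.bone[1]

    def test_reference_regions_sample_pure_materials(self, clean_spec, clean_phantom):
        pre, *_ , gt = clean_phantom
        inten = clean_spec.intensities
        assert np.all(pre.voxels[gt.reference_regions["air"]] == inten.air)
        assert np.all(pre.voxels[gt.reference_regions["tissue"]] == inten.tissue)
        assert np.all(pre.voxels[gt.reference_regions["bone"]] == inten.bone)


class TestAnalyticModel:
    def test_factor_one_gives_zero_increase(self):
        assert true_air_increase_percent(PhantomSpec(dilation_factor=1.0)) == 0.0

    @pytest.mark.parametrize("target", [20.0, 55.0, 100.0])
    def test_tuner_inverts_analytic_increase(self, target):
        spec = dilation_factor_for_air_increase(PhantomSpec(), target)
        assert true_air_increase_percent(spec) == pytest.approx(target, abs=1e-6)

    @pytest.mark.parametrize("target", [33.0, 98.0])
    def test_cylinder_region_tuning(self, target):
        spec = dilation_factor_for_air_increase(PhantomSpec(), target, "cylinder")
        assert true_air_increase_percent(spec, "cylinder") == pytest.approx(target, abs=1e-6)

    def test_analytic_matches_voxel_counts(self):
        # discretized mask counts should track the continuous volume model
        spec = PhantomSpec(dilation_factor=1.6)
        gt = compute_ground_truth(spec)
        assert gt.percent_air_increase() == pytest.approx(
            true_air_increase_percent(spec), abs=5.0
        )

    def test_cylinder_increase_exceeds_global(self):
        # dilation is concentrated in the marker-to-marker span
        spec = PhantomSpec(dilation_factor=1.7)
        assert true_air_increase_percent(spec, "cylinder") > true_air_increase_percent(spec)


class TestSeriesExport:
    def test_write_read_round_trip(self, clean_phantom, tmp_path):
        pre, *_ = clean_phantom
        paths = write_phantom_series(pre, tmp_path)
        assert len(paths) == pre.shape[0]
        back = read_dicom_series(tmp_path)
        assert np.array_equal(back.voxels, pre.voxels)
        assert back.spacing == pytest.approx(pre.spacing)
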