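"""Landmark plane geometry, stack extraction, and rotation."""

import itertools
import json

import numpy as np
import pytest

from etquant.reslice import (
    LandmarkSet,
    PlaneFrame,
    SliceStack,
    extract_stack,
    load_landmarks,
    plane_from_landmarks,
    rotate_point_2d,
    rotate_to_vertical,
    save_landmarks,
)
from etquant.volume import Volume

SPACING = (0.625, 0.3125, 0.3125)


def lm(p1, p2, p3, **kw):
    return LandmarkSet(p1, p2, p3, **kw)


class TestPlaneFromLandmarks:
    def test_axis_aligned_triple_gives_axis_normal(self):
        frame = plane_from_landmarks(
            lm((0, 0, 0), (0, 10, 0), (0, 0, 10)), (1.0, 1.0, 1.0)
        )
        assert abs(frame.normal) == pytest.approx([1.0, 0.0, 0.0])

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="degenerate plane"):
            plane_from_landmarks(lm((0, 0, 0), (0, 5, 5), (0, 10, 10)), (1, 1, 1))

    def test_tiny_triangle_rejected(self):
        # area well under 1 mm^2 at this spacing
        with pytest.raises(ValueError, match="degenerate plane"):
            plane_from_landmarks(
                lm((0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)), (0.625, 0.3125, 0.3125)
            )

    def test_random_triples_lie_in_plane(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 40, size=(3, 3))
            try:
                frame = plane_from_landmarks(lm(*map(tuple, pts)), SPACING)
            except ValueError:
                continue  # degenerate draw
            for p in pts:
                d = abs((p * SPACING - frame.origin) @ frame.normal)
                assert d < 1e-6
            for a, b in itertools.combinations(
                (frame.in_plane_u, frame.in_plane_v, frame.normal), 2
            ):
                assert abs(a @ b) < 1e-9
                assert np.linalg.norm(a) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        pts = [tuple(p) for p in rng.uniform(0, 40, size=(3, 3))]
        ref = plane_from_landmarks(lm(*pts), SPACING)
        for perm in itertools.permutations(pts):
            frame = plane_from_landmarks(lm(*perm), SPACING)
            assert frame.normal == pytest.approx(ref.normal)
            assert frame.in_plane_u == pytest.approx(ref.in_plane_u)
            assert frame.in_plane_v == pytest.approx(ref.in_plane_v)
            assert frame.origin == pytest.approx(ref.origin)

    def test_balloon_axis_orients_vertical(self):
        frame = plane_from_landmarks(
            lm(
                (0, 0, 0),
                (0, 20, 0),
                (0, 0, 20),
                torus_tip=(0, 2, 2),
                balloon_tip=(0, 18, 2),
            ),
            (1.0, 1.0, 1.0),
        )
        # v points from torus toward tip: +y here
        assert frame.in_plane_v == pytest.approx([0.0, 1.0, 0.0])


class TestExtractStack:
    def identity_frame(self, vol, center_slice):
        origin = np.array(
            [
                center_slice * vol.spacing[0],
                (vol.shape[1] - 1) / 2 * vol.spacing[1],
                (vol.shape[2] - 1) / 2 * vol.spacing[2],
            ]
        )
        return PlaneFrame(
            origin,
            np.array([0.0, 0.0, 1.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([1.0, 0.0, 0.0]),
            vol.spacing[0],
        )

    def test_native_alignment_is_bit_exact(self, rng):
        vox = rng.integers(0, 256, size=(9, 16, 12)).astype(float)
        vol = Volume(vox, SPACING, "gray8")
        frame = self.identity_frame(vol, 4)
        stack = extract_stack(
            vol, frame, half_count=4, size_px=(16, 12), pixel_spacing=SPACING[1]
        )
        for k in range(9):
            assert np.array_equal(stack.images[k], vox[k])

    def test_25_images_for_half_count_12(self, rng):
        vol = Volume(rng.integers(0, 256, (30, 8, 8)).astype(float), SPACING, "gray8")
        stack = extract_stack(vol, self.identity_frame(vol, 15), 12, (8, 8))
        assert len(stack) == 25
        assert stack.offsets[12] == 0.0

    def test_half_count_zero_gives_single_image(self, rng):
        vol = Volume(rng.integers(0, 256, (5, 8, 8)).astype(float), SPACING, "gray8")
        stack = extract_stack(vol, self.identity_frame(vol, 2), 0, (8, 8))
        assert len(stack) == 1

    def test_out_of_volume_samples_are_zero(self, rng):
        vol = Volume(np.full((4, 4, 4), 200.0), (1, 1, 1), "gray8")
        frame = PlaneFrame(
            np.array([1.5, 1.5, 1.5]),
            np.array([0.0, 0.0, 1.0]),
            np.array([0.0, 1.0, 0.0]),
            np.array([1.0, 0.0, 0.0]),
            1.0,
        )
        stack = extract_stack(vol, frame, 0, (40, 40), pixel_spacing=1.0)
        corners = stack.center[[0, 0, -1, -1], [0, -1, 0, -1]]
        assert np.all(corners == 0.0)
        assert stack.center[20, 20] == 200.0

    def test_matched_geometry_across_volumes(self, rng):
        # same frame on two volumes: identical shapes, offsets, spacing
        v1 = Volume(rng.integers(0, 256, (9, 16, 12)).astype(float), SPACING, "gray8")
        v2 = Volume(rng.integers(0, 256, (9, 16, 12)).astype(float), SPACING, "gray8")
        frame = self.identity_frame(v1, 4)
        s1 = extract_stack(v1, frame, 4, (16, 12))
        s2 = extract_stack(v2, frame, 4, (16, 12))
        assert s1.center.shape == s2.center.shape
        assert np.array_equal(s1.offsets, s2.offsets)
        assert s1.pixel_spacing == s2.pixel_spacing


class TestRotation:
    def make_stack(self, img):
        return SliceStack([img], np.array([0.0]), (1.0, 1.0))

    def test_vertical_axis_is_identity(self):
        img = np.zeros((32, 32))
        img[10:20, 16] = 100.0
        rotated, angle = rotate_to_vertical(self.make_stack(img), (1.0, 0.0))
        assert angle == 0.0
        assert np.array_equal(rotated.images[0], img)

    def test_horizontal_bar_becomes_vertical(self):
        img = np.zeros((64, 64))
        img[30, 10:50] = 200.0
        rotated, angle = rotate_to_vertical(self.make_stack(img), (0.0, 1.0))
        assert abs(angle) == pytest.approx(90.0)
        col_mass = rotated.images[0].sum(axis=0)
        assert col_mass.max() > 0.9 * img.sum()  # mass concentrated in one column

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            rotate_to_vertical(self.make_stack(np.zeros((8, 8))), (0.0, 0.0))

    def test_point_map_follows_image_content(self, rng):
        for _ in range(5):
            r, c = rng.integers(15, 45, size=2)
            img = np.zeros((64, 64))
            img[r, c] = 255.0
            axis = rng.normal(size=2)
            rotated, angle = rotate_to_vertical(self.make_stack(img), tuple(axis))
            mapped = rotate_point_2d((r, c), angle, (64, 64))
            peak = np.unravel_index(np.argmax(rotated.images[0]), (64, 64))
            assert np.linalg.norm(mapped - np.asarray(peak)) < 1.0

    def test_rotation_straightens_phantom_lumen(self, clean_analysis):
        # after rotation the air column's per-row centroid barely drifts
        img = clean_analysis.stack_pre.center
        roi = clean_analysis.rois["longest"]
        cols = []
        for row in range(roi.row_min, roi.row_max + 1):
            line = img[row, roi.col_min : roi.col_max + 1]
            air = np.where(line <= 31)[0]
            if air.size:
                cols.append(air.mean())
        assert np.std(cols) < 1.0


class TestLandmarkIO:
    def test_round_trip(self, tmp_path):
        lms = LandmarkSet(
            (1.0, 2.0, 3.0),
            (4.0, 5.0, 6.0),
            (7.0, 8.0, 9.0),
            torus_tip=(0.5, 1.5, 2.5),
        )
        save_landmarks(lms, tmp_path / "lm.json")
        back = load_landmarks(tmp_path / "lm.json")
        assert back == lms

    def test_missing_convention_rejected(self, tmp_path):
        data = {
            "medial_pterygoid_plate": [0, 0, 0],
            "opposite_pterygoid_plate": [0, 1, 0],
            "sphenoid_spine": [0, 0, 1],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="coordinate_convention"):
            load_landmarks(path)
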