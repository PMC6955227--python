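"""Pose estimation: orientation, limb extraction, endpoints, angle conventions."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from frogswim import pose as fp
from frogswim import synth
from frogswim._geometry import angle_from_offset, unit_from_angle
from conftest import recovered_angle_errors, run_pose_pipeline


def ellipse_mask(shape=(200, 200), center=(100, 100), a=60, b=25, deg_from_vertical=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    th = np.deg2rad(deg_from_vertical)
    u = (yy - center[0]) * np.cos(th) + (xx - center[1]) * np.sin(th)
    v = -(yy - center[0]) * np.sin(th) + (xx - center[1]) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1


class TestOrientation:
    def test_vertical_ellipse_is_ninety_degrees(self):
        assert fp.estimate_orientation(ellipse_mask(), erosion_radius=3) == pytest.approx(90.0, abs=0.5)

    def test_tilted_ellipse(self):
        # 30 degrees from vertical = 60 degrees from horizontal
        mask = ellipse_mask(deg_from_vertical=30.0)
        assert fp.estimate_orientation(mask, erosion_radius=3) == pytest.approx(60.0, abs=1.0)

    def test_circle_degenerate(self):
        mask = ellipse_mask(a=40, b=40)
        with pytest.raises(fp.PoseError, match="principal axis"):
            fp.estimate_orientation(mask, erosion_radius=3)

    def test_empty_after_erosion(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 25] = True
        with pytest.raises(fp.PoseError, match="empty"):
            fp.estimate_orientation(mask, erosion_radius=5)

    def test_recovers_rendered_heading(self, short_video):
        frames, gt = short_video
        for idx, (p, _) in list(run_pose_pipeline(frames).items())[:10]:
            # a heading of phi degrees tilts the body axis to 90 + phi
            # versus the horizontal (image rows increase downward)
            want = (90.0 + gt.frames.heading_deg[idx]) % 180.0
            got = p.orientation % 180.0
            delta = min(abs(got - want), 180 - abs(got - want))
            assert delta < 2.0


class TestNormalizeOrientation:
    def test_heavier_half_goes_to_bottom(self):
        mask = ellipse_mask()
        mask[150:170, 95:105] = True  # posterior lump below center
        oriented, rot = fp.normalize_orientation(mask, 90.0)
        rows = np.nonzero(oriented)[0]
        split = ndimage.center_of_mass(oriented)[0]
        assert (rows > split).sum() > (rows < split).sum()
        # the same mask upside down gets flipped back
        flipped, rot2 = fp.normalize_orientation(mask[::-1, ::-1], 90.0)
        assert (np.nonzero(flipped)[0] > ndimage.center_of_mass(flipped)[0]).sum() > (
            np.nonzero(flipped)[0] < ndimage.center_of_mass(flipped)[0]
        ).sum()

    def test_symmetric_mask_not_flipped(self):
        """Strict inequality: a perfectly balanced mask keeps its orientation."""
        mask = ellipse_mask()
        _, rot = fp.normalize_orientation(mask, 90.0)
        assert rot == pytest.approx(0.0)

    def test_nonfinite_angle_rejected(self):
        with pytest.raises(ValueError):
            fp.normalize_orientation(ellipse_mask(), np.nan)


class TestExtractLimbs:
    def test_synthetic_frame_has_four_limb_components(self, short_video):
        from skimage import measure

        frames, _ = short_video
        from frogswim import segment

        area = segment.calibrate_area(frames, seed=0)
        er = fp.default_erosion_radius(area.calibration_area)
        det = segment.track_video(frames[:1], area, frame_step=1)[0]
        angle = fp.estimate_orientation(det.mask, er)
        oriented, _ = fp.normalize_orientation(det.mask, angle, erosion_radius=er)
        limbs, joints = fp.extract_limbs(oriented, er)
        assert measure.label(limbs, connectivity=2).max() == 4
        assert joints.any()

    def test_limbless_ellipse_raises(self):
        with pytest.raises(fp.PoseError, match="no limb"):
            fp.extract_limbs(ellipse_mask(), erosion_radius=5)


class TestSkeletonEndpoints:
    def test_straight_line_two_endpoints(self):
        mask = np.zeros((40, 60), bool)
        mask[20, 10:30] = True
        eps = fp.skeleton_endpoints(mask)
        assert len(eps) == 2
        assert {tuple(p) for p in eps} == {(10.0, 20.0), (29.0, 20.0)}

    def test_l_shape_two_endpoints(self):
        """The corner of an L is not an endpoint."""
        mask = np.zeros((40, 60), bool)
        mask[20, 10:31] = True
        mask[10:21, 30] = True
        eps = fp.skeleton_endpoints(mask)
        assert len(eps) == 2
        assert {tuple(p) for p in eps} == {(10.0, 20.0), (30.0, 10.0)}

    def test_empty_mask_raises(self):
        with pytest.raises(fp.PoseError):
            fp.skeleton_endpoints(np.zeros((10, 10), bool))

    def test_synthetic_endpoints_near_true_feet(self, short_video):
        frames, gt = short_video
        errs = recovered_angle_errors(frames, gt)
        assert len(errs) > 30  # most frames produced a valid pair


class TestAssignLimbs:
    def test_one_endpoint_per_quadrant(self):
        joints = np.zeros((100, 100), bool)
        for x, y in ((40, 40), (60, 40), (40, 60), (60, 60)):
            joints[y - 1 : y + 2, x - 1 : x + 2] = True
        eps = np.array([[20.0, 20.0], [80.0, 20.0], [20.0, 80.0], [80.0, 80.0]])
        p = fp.assign_limbs(eps, joints, centroid=(50.0, 50.0))
        assert p.limb_endpoints["fore_left"] == (20.0, 20.0)
        assert p.limb_endpoints["fore_right"] == (80.0, 20.0)
        assert p.limb_endpoints["hind_left"] == (20.0, 80.0)
        assert p.limb_endpoints["hind_right"] == (80.0, 80.0)
        assert all(p.valid_limbs.values())

    def test_furthest_from_joint_wins_within_quadrant(self):
        joints = np.zeros((100, 100), bool)
        joints[59:62, 59:62] = True  # hind-right joint at (60, 60)
        near = [68.0, 60.0]  # 8 px from joint
        far = [75.0, 60.0]  # 15 px
        p = fp.assign_limbs(np.array([near, far]), joints, centroid=(50.0, 50.0))
        assert p.limb_endpoints["hind_right"] == tuple(far)

    def test_empty_quadrant_invalid(self):
        joints = np.zeros((100, 100), bool)
        joints[59:62, 59:62] = True
        p = fp.assign_limbs(np.array([[80.0, 80.0]]), joints, centroid=(50.0, 50.0))
        assert p.valid_limbs["hind_right"]
        assert not p.valid_limbs["fore_left"]
        assert not p.valid_limbs["hind_left"]


class TestAnglePair:
    def test_convention_anchors(self):
        """Feet pointing laterally give 0 deg; straight posterior gives 90."""
        p = fp.Pose(0, centroid=(100.0, 100.0), orientation=90.0)
        p.valid_limbs = {"hind_right": True, "hind_left": True}
        p.limb_endpoints = {"hind_right": (160.0, 100.0), "hind_left": (40.0, 100.0)}
        pair = fp.compute_angle_pair(p)
        assert pair.alpha_right == pytest.approx(0.0)
        assert pair.alpha_left == pytest.approx(0.0)
        p.limb_endpoints = {"hind_right": (100.0, 160.0), "hind_left": (100.0, 160.0)}
        pair = fp.compute_angle_pair(p)
        assert pair.alpha_right == pytest.approx(90.0)
        assert pair.alpha_left == pytest.approx(90.0)

    def test_mirror_posture_gives_equal_angles(self):
        p = fp.Pose(0, centroid=(100.0, 100.0), orientation=90.0)
        p.valid_limbs = {"hind_right": True, "hind_left": True}
        for alpha in (10.0, 45.0, 120.0):
            r = 70.0 * unit_from_angle(alpha, "right") + 100.0
            l = 70.0 * unit_from_angle(alpha, "left") + 100.0
            p.limb_endpoints = {"hind_right": tuple(r), "hind_left": tuple(l)}
            pair = fp.compute_angle_pair(p)
            assert pair.alpha_right == pytest.approx(pair.alpha_left, abs=1e-9)
            assert pair.alpha_right == pytest.approx(alpha, abs=1e-9)

    def test_invalid_hindlimb_invalid_pair(self):
        p = fp.Pose(0, centroid=(100.0, 100.0), orientation=90.0)
        p.valid_limbs = {"hind_right": True, "hind_left": False}
        p.limb_endpoints = {"hind_right": (160.0, 100.0)}
        assert not fp.compute_angle_pair(p).valid


class TestEndToEnd:
    def test_angle_recovery_short_video(self, short_video):
        frames, gt = short_video
        errs = recovered_angle_errors(frames, gt)
        assert np.abs(errs).mean() < 3.0
        assert abs(errs.mean()) < 1.0  # no systematic bias

    def test_mirror_flip_swaps_traces(self, short_video):
        """Horizontally flipping the video swaps the right/left angle traces."""
        frames, _ = short_video
        base = {i: pair for i, (_, pair) in run_pose_pipeline(frames).items() if pair.valid}
        mirrored = {
            i: pair
            for i, (_, pair) in run_pose_pipeline([f[:, ::-1] for f in frames]).items()
            if pair.valid
        }
        common = sorted(set(base) & set(mirrored))
        assert len(common) > 25
        swap_err = [
            abs(mirrored[i].alpha_right - base[i].alpha_left)
            + abs(mirrored[i].alpha_left - base[i].alpha_right)
            for i in common
        ]
        assert np.mean(swap_err) / 2 < 1.5
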