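"""Shared fixtures: synthetic videos rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from frogswim import segment, synth
from frogswim.pose import PoseError, compute_angle_pair, default_erosion_radius, estimate_pose


@pytest.fixture(scope="session")
def render_params():
    return synth.RenderParams()


def _make_video(label: str, n_frames: int, seed: int):
    model = synth.default_motion_model(label, seed=seed)
    traces = synth.generate_traces(model, n_frames=n_frames, fps=60, seed=seed + 10)
    frames, gt = synth.render_video(traces)
    return frames, gt


@pytest.fixture(scope="session")
def uninjured_video():
    """200-frame uninjured swim at default parameters, with ground truth."""
    return _make_video("uninjured", 200, seed=1)


@pytest.fixture(scope="session")
def hemisected_video():
    return _make_video("hemisected", 200, seed=1)


@pytest.fixture(scope="session")
def transected_video():
    return _make_video("transected", 200, seed=1)


@pytest.fixture(scope="session")
def short_video():
    """A 40-frame uninjured clip for cheap pipeline-level tests."""
    return _make_video("uninjured", 40, seed=5)


def run_pose_pipeline(frames, frame_step: int = 1):
    """Minimal segment+pose run; returns {frame_index: (pose, pair)}."""
    area = segment.calibrate_area(frames, seed=0)
    erosion = default_erosion_radius(area.calibration_area)
    out = {}
    for det in segment.track_video(frames, area, frame_step=frame_step):
        if not det.valid:
            continue
        try:
            pose = estimate_pose(det, erosion_radius=erosion)
        except PoseError:
            continue
        out[det.frame_index] = (pose, compute_angle_pair(pose))
    return out


def recovered_angle_errors(frames, gt):
    """Per-frame (err_right, err_left) against the ground-truth sidecar."""
    gtdf = gt.frames
    errs = []
    for idx, (_, pair) in run_pose_pipeline(frames).items():
        if pair.valid:
            errs.append(
                (
                    pair.alpha_right - gtdf.alpha_right[idx],
                    pair.alpha_left - gtdf.alpha_left[idx],
                )
            )
    return np.asarray(errs)
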