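"""The five-step video pipeline: acquire, segment, pose, summarize, classify.

``run_pipeline`` processes one video end to end and writes every stage's
artifact into an output directory with fixed file names, so a
manifest-driven batch run can resume from any stage.  ``batch_evaluate``
reproduces the classifier-comparison table over a labeled cohort.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import segment as seg
from .classify import FeatureDataset, comparison_table, predict
from .config import PipelineConfig
from .kinematics import (
    AnglePair,
    KinematicFeatures,
    build_histogram,
    extract_features,
    features_from_traces,
    plot_heatmap,
)
from .pose import PoseError, compute_angle_pair, default_erosion_radius, estimate_pose, poses_to_dataframe
from .synth import ClassLabel, default_motion_model, generate_traces

logger = logging.getLogger("frogswim")

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "extract_video_features",
    "batch_evaluate",
    "synthetic_feature_cohort",
]


@dataclass
class PipelineResult:
    """Artifacts of one video run."""

    detections: pd.DataFrame
    poses: pd.DataFrame
    features: KinematicFeatures
    predicted_label: str | None
    out_dir: Path | None


def _pose_erosion_radius(config: PipelineConfig, area_range: seg.AreaRange) -> int:
    if config.pose.erosion_radius is not None:
        return config.pose.erosion_radius
    return default_erosion_radius(area_range.calibration_area, config.pose.erosion_factor)


def extract_video_features(video, config: PipelineConfig | None = None):
    """Segment, track and pose a video; return (detections, poses, pairs, features).

    Frames whose pose cannot be estimated are skipped (logged with their
    frame index), exactly as invalid frames are skipped when features are
    accumulated.
    """
    config = config or PipelineConfig()
    sc = config.segment
    t0 = time.perf_counter()
    area_range = seg.calibrate_area(
        video,
        n_frames=sc.calibration_frames,
        seed=config.seed,
        threshold_method=sc.threshold_method,
        fixed_value=sc.fixed_value,
        assume_dark_foreground=sc.assume_dark_foreground,
    )
    logger.info("calibration area %.0f px^2 (%.2fs)", area_range.calibration_area, time.perf_counter() - t0)

    t0 = time.perf_counter()
    detections = seg.track_video(
        video,
        area_range,
        frame_step=sc.frame_step,
        window_scale=sc.window_scale,
        threshold_method=sc.threshold_method,
        fixed_value=sc.fixed_value,
        assume_dark_foreground=sc.assume_dark_foreground,
    )
    n_valid = sum(d.valid for d in detections)
    logger.info("tracked %d/%d frames (%.2fs)", n_valid, len(detections), time.perf_counter() - t0)
    if n_valid == 0:
        raise ValueError("no valid detections in the whole video; nothing to analyze")

    erosion_radius = _pose_erosion_radius(config, area_range)
    t0 = time.perf_counter()
    poses = []
    pairs: list[AnglePair] = []
    right_pts, left_pts = [], []
    for det in detections:
        if not det.valid:
            continue
        try:
            pose = estimate_pose(
                det,
                erosion_radius=erosion_radius,
                dilation_radius=config.pose.dilation_radius,
                min_limb_area=config.pose.min_limb_area,
            )
        except PoseError as exc:
            logger.warning("frame %d: pose failed (%s); skipping", det.frame_index, exc)
            continue
        poses.append(pose)
        pair = compute_angle_pair(pose)
        pairs.append(pair)
        if pair.valid:
            right_pts.append(pose.endpoint_offset("hind_right"))
            left_pts.append(pose.endpoint_offset("hind_left"))
    logger.info("posed %d frames (%.2fs)", len(poses), time.perf_counter() - t0)

    kc = config.kinematics
    features = extract_features(
        pairs,
        foot_positions_right=np.asarray(right_pts) if right_pts else None,
        foot_positions_left=np.asarray(left_pts) if left_pts else None,
        centroid=(0.0, 0.0),
        correlation=kc.correlation,
        fit_intercept=kc.fit_intercept,
        kde_bandwidth=kc.kde_bandwidth,
        gaussian_sigma=kc.gaussian_sigma,
        density_threshold_fraction=kc.density_threshold_fraction,
    )
    return detections, poses, pairs, features


def run_pipeline(
    video,
    config: PipelineConfig | None = None,
    classifier=None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Process one video end to end, optionally classifying it.

    Writes ``detections.csv``, ``pose.csv``, ``features.json`` and
    ``heatmap.png`` into ``out_dir`` (if given).  ``classifier`` is a
    model trained on the four-feature vector; when omitted the run is
    features-only and no label is emitted.
    """
    config = config or PipelineConfig()
    detections, poses, pairs, features = extract_video_features(video, config)
    det_df = seg.detections_to_dataframe(detections)
    pose_df = poses_to_dataframe(poses)

    label = None
    if classifier is not None:
        label = str(predict(classifier, features.as_vector())[0])

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        det_df.to_csv(out_path / "detections.csv", index=False)
        pose_df.to_csv(out_path / "pose.csv", index=False)
        np.savetxt(out_path / "histogram.csv", build_histogram(pairs).counts, fmt="%d", delimiter=",")
        payload = features.to_dict()
        if label is not None:
            payload["predicted_label"] = label
        (out_path / "features.json").write_text(json.dumps(payload, indent=2))
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = plot_heatmap(build_histogram(pairs), slope=features.f2_symmetry)
        ax.figure.savefig(out_path / "heatmap.png", dpi=120)
        plt.close(ax.figure)

    return PipelineResult(det_df, pose_df, features, label, out_path)


def synthetic_feature_cohort(
    n_per_class: int = 30,
    n_frames: int = 600,
    fps: float = 60.0,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> FeatureDataset:
    """Feature cohort computed from synthetic ground-truth traces.

    One animal per (class, seed offset): a class-typical motion model
    with per-animal variation generates traces, and the four features are
    computed directly from the recorded ground truth — the fast cohort
    used to exercise the classification harness without rendering video.
    """
    kc = (config or PipelineConfig()).kinematics
    rows, labels = [], []
    for label in ClassLabel:
        for i in range(n_per_class):
            animal_seed = (int(seed) * 100003 + i * 1009 + zlib.crc32(label.value.encode()) % 997) & 0x7FFFFFFF
            model = default_motion_model(label, seed=animal_seed)
            traces = generate_traces(model, n_frames=n_frames, fps=fps, seed=animal_seed + 1)
            feats = features_from_traces(
                traces,
                correlation=kc.correlation,
                fit_intercept=kc.fit_intercept,
                kde_bandwidth=kc.kde_bandwidth,
                gaussian_sigma=kc.gaussian_sigma,
                density_threshold_fraction=kc.density_threshold_fraction,
            )
            rows.append(feats.as_vector())
            labels.append(label.value)
    return FeatureDataset(np.asarray(rows), np.asarray(labels), ("f1", "f2", "f3", "f4"))


def batch_evaluate(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Classifier-comparison table over a labeled cohort.

    The manifest is a CSV (or DataFrame) with a ``label`` column and
    either precomputed feature columns ``f1..f4`` or a ``path`` column of
    videos to process.  Cross-validation is run for every (classifier,
    feature set) combination in the config and the table written as CSV.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(manifest) if not isinstance(manifest, pd.DataFrame) else manifest.copy()
    if "label" not in df.columns:
        raise ValueError("manifest must have a 'label' column")
    if df["label"].nunique() < 2:
        raise ValueError("manifest must contain at least two classes")

    feature_cols = ["f1", "f2", "f3", "f4"]
    if not set(feature_cols) <= set(df.columns):
        if "path" not in df.columns:
            raise ValueError("manifest needs either f1..f4 columns or a 'path' column")
        feats = []
        for path in df["path"]:
            *_, f = extract_video_features(path, config)
            feats.append(f.as_vector())
        df[feature_cols] = np.asarray(feats)

    data = FeatureDataset.from_dataframe(df, feature_cols)
    cc = config.classify
    table = comparison_table(
        data,
        classifiers=cc.classifiers,
        feature_sets={k: tuple(v) for k, v in cc.feature_sets.items()},
        n_folds=cc.n_folds,
        n_repeats=cc.n_repeats,
        seed=config.seed,
        standardize=cc.standardize,
    )
    if out_path is not None:
        table.to_csv(out_path)
    return table
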