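"""Pipeline configuration: every tunable in one validated, round-trippable object."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class SegmentConfig(BaseModel):
    """Segmentation and tracking tunables."""

    model_config = ConfigDict(extra="forbid")

    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_value: float | None = None
    assume_dark_foreground: bool = True
    calibration_frames: int = 6
    frame_step: int = 2
    window_scale: float = 3.0  # window side as a multiple of the calibrated disc diameter


class PoseConfig(BaseModel):
    """Orientation and limb-detection tunables."""

    model_config = ConfigDict(extra="forbid")

    erosion_factor: float = 0.25  # of the calibrated equivalent-disc radius
    erosion_radius: int | None = None  # explicit override in pixels
    dilation_radius: int = 2
    min_limb_area: int = 8


class KinematicsConfig(BaseModel):
    """Feature-extraction tunables."""

    model_config = ConfigDict(extra="forbid")

    correlation: str = "pearson"  # or "spearman"
    fit_intercept: bool = False  # symmetry regression through the origin by default
    kde_bandwidth: float | None = 3.0  # pixels; None = Silverman rule
    gaussian_sigma: float = 1.0
    density_threshold_fraction: float = 0.05


class ClassifyConfig(BaseModel):
    """Cross-validation and classifier tunables."""

    model_config = ConfigDict(extra="forbid")

    n_folds: int = 10
    n_repeats: int = 10
    standardize: bool = True
    classifiers: list[str] = Field(
        default_factory=lambda: [
            "mindist", "lda", "qda", "knn1", "knn3", "knn5",
            "mahalanobis", "svm-linear", "svm-rbf", "nnet",
        ]
    )
    feature_sets: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "f1-f2": ["f1", "f2"],
            "f3-f4": ["f3", "f4"],
            "all": ["f1", "f2", "f3", "f4"],
        }
    )


class PipelineConfig(BaseModel):
    """All pipeline tunables; unknown keys are rejected on load."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    segment: SegmentConfig = Field(default_factory=SegmentConfig)
    pose: PoseConfig = Field(default_factory=PoseConfig)
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    classify: ClassifyConfig = Field(default_factory=ClassifyConfig)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
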