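"""Detect and track the froglet body across video frames.

The animal is darker than the illuminated tank background, and the blue
channel separates the two best, so segmentation is a blue-channel
threshold.  A per-video *area calibration* measures the animal's pixel
area in six randomly sampled frames; the median defines a +-10%
acceptance band, and every connected component outside that band is
rejected during tracking.  Among surviving components, the one closest to
the previous detection is chosen, and a fixed-size window centered on it
is carried to the next processed frame (every second frame by default).

The region-of-interest detector used during calibration is a pluggable
seam (:class:`RoiDetector`); the default proposes the whole frame and
relies on thresholding, which is sufficient on clean backgrounds.  A
learned detector can be plugged in without touching the rest of the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure

from . import io as fio

__all__ = [
    "AreaRange",
    "Detection",
    "RoiDetector",
    "FullFrameRoiDetector",
    "PolarityError",
    "threshold_blue",
    "calibrate_area",
    "detect_froglet",
    "track_video",
    "detections_to_dataframe",
]


class PolarityError(ValueError):
    """The thresholded foreground covers most of the image.

    The segmenter assumes the animal is darker than the background; if
    the mask majority is foreground the polarity is almost certainly
    inverted.  Pass ``assume_dark_foreground=False`` to override.
    """


@dataclass(frozen=True)
class AreaRange:
    """Calibrated animal area with the +-10% acceptance band (pixels^2)."""

    calibration_area: float

    @property
    def lower_bound(self) -> float:
        return 0.9 * self.calibration_area

    @property
    def upper_bound(self) -> float:
        return 1.1 * self.calibration_area

    def __contains__(self, area: float) -> bool:
        return self.lower_bound <= area <= self.upper_bound

    def window_side(self, scale: float = 3.0) -> int:
        """Side of the fixed tracking window, in pixels.

        ``scale`` multiplies the diameter of the disc whose area equals
        the calibration area.
        """
        return int(round(scale * 2.0 * np.sqrt(self.calibration_area / np.pi)))


@dataclass
class Detection:
    """One tracked frame: a binary mask inside a fixed window.

    ``window_origin`` is the (x, y) of the window's top-left corner in
    the full frame; ``centroid`` and ``area`` refer to the chosen
    component in full-frame coordinates.  ``valid`` is False when no
    component survived the area filter, in which case the previous
    window is carried forward so tracking can re-acquire.
    """

    frame_index: int
    mask: np.ndarray | None
    window_origin: tuple[int, int]
    window_size: int
    centroid: tuple[float, float] | None
    area: float
    valid: bool


class RoiDetector(Protocol):
    """Pluggable contract: frame -> candidate bounding box or None.

    A bounding box is ``(x0, y0, x1, y1)`` in pixels, half-open, clipped
    to the frame.  This seam is where a learned detector would slot in.
    """

    def __call__(self, frame: np.ndarray) -> tuple[int, int, int, int] | None: ...


class FullFrameRoiDetector:
    """Default ROI detector: propose the entire frame."""

    def __call__(self, frame: np.ndarray) -> tuple[int, int, int, int]:
        h, w = frame.shape[:2]
        return (0, 0, w, h)


def threshold_blue(
    frame: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
    assume_dark_foreground: bool = True,
) -> np.ndarray:
    """Binary animal mask from the blue channel of an RGB frame.

    Foreground (the animal) is where blue intensity falls at or below the
    threshold — the animal appears white on black in the mask.  A frame
    with a constant blue channel yields an empty mask (degenerate input);
    a mask whose foreground covers more than half the frame raises
    :class:`PolarityError` unless ``assume_dark_foreground`` is False,
    in which case the mask is inverted.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError("threshold_blue expects an RGB frame with three channels")
    if method == "fixed" and fixed_value is None:
        raise ValueError("fixed thresholding requires fixed_value")
    if method not in {"otsu", "fixed"}:
        raise ValueError(f"unknown threshold method {method!r}")
    blue = frame[:, :, 2]
    if np.ptp(blue) == 0:
        return np.zeros(blue.shape, dtype=bool)
    thresh = filters.threshold_otsu(blue) if method == "otsu" else fixed_value
    mask = blue <= thresh
    if mask.mean() > 0.5:
        if assume_dark_foreground:
            raise PolarityError(
                "thresholded foreground covers most of the frame; the animal "
                "appears lighter than the background (set "
                "assume_dark_foreground=False to invert)"
            )
        mask = ~mask
    return mask


def _component_table(mask: np.ndarray) -> list[tuple[int, float, tuple[float, float]]]:
    """(label, area, centroid (x, y)) of each connected component."""
    labels = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        out.append((region.label, float(region.area), (float(cx), float(cy))))
    return out


def calibrate_area(
    video,
    detector: RoiDetector | None = None,
    n_frames: int = 6,
    seed: int = 0,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    assume_dark_foreground: bool = True,
) -> AreaRange:
    """Median animal area over randomly sampled frames, with +-10% band.

    ``n_frames`` frames are drawn uniformly without replacement (seeded);
    in each, the largest thresholded component inside the detector's
    proposed region is measured.  The calibration area is the median of
    the measurements, robust to the occasional bad sample.
    """
    frames = fio.load_frames(video)
    if len(frames) < n_frames:
        raise ValueError(f"video has {len(frames)} frames; calibration needs {n_frames}")
    detector = detector or FullFrameRoiDetector()
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    picks = rng.choice(len(frames), size=n_frames, replace=False)

    areas = []
    for idx in sorted(picks):
        frame = frames[idx]
        box = detector(frame)
        if box is None:
            continue
        x0, y0, x1, y1 = box
        mask = threshold_blue(
            frame[y0:y1, x0:x1],
            method=threshold_method,
            fixed_value=fixed_value,
            assume_dark_foreground=assume_dark_foreground,
        )
        comps = _component_table(mask)
        if comps:
            areas.append(max(a for _, a, _ in comps))
    if not areas:
        raise ValueError("no animal found in any sampled calibration frame")
    return AreaRange(float(np.median(areas)))


def _window_bounds(center: tuple[float, float], side: int, shape: tuple[int, int]) -> tuple[int, int]:
    """Top-left (x, y) of a side x side window clipped into the frame."""
    h, w = shape
    x0 = int(round(center[0] - side / 2))
    y0 = int(round(center[1] - side / 2))
    x0 = min(max(x0, 0), max(w - side, 0))
    y0 = min(max(y0, 0), max(h - side, 0))
    return x0, y0


def detect_froglet(
    frame: np.ndarray,
    area_range: AreaRange,
    prev: Detection | None = None,
    frame_index: int = 0,
    window_scale: float = 3.0,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    assume_dark_foreground: bool = True,
) -> Detection:
    """Detect the animal in one frame, guided by the previous detection.

    The previous detection's window restricts the search; connected
    components are filtered by the calibrated area band, and among the
    survivors the one whose centroid is nearest the previous centroid is
    chosen (the largest one when there is no previous detection; equal
    distances break toward the lower component label).  Absence is not an
    error: an invalid :class:`Detection` carries the previous window
    forward.
    """
    frame = np.asarray(frame)
    h, w = frame.shape[:2]
    side = min(area_range.window_side(window_scale), min(h, w))

    if prev is not None:
        sx, sy = prev.window_origin
        sw = prev.window_size
        search = frame[sy : sy + sw, sx : sx + sw]
        prev_centroid = prev.centroid
    else:
        sx = sy = 0
        search = frame
        prev_centroid = None

    mask = threshold_blue(
        search,
        method=threshold_method,
        fixed_value=fixed_value,
        assume_dark_foreground=assume_dark_foreground,
    )
    survivors = [
        (label, area, (cx + sx, cy + sy))
        for label, area, (cx, cy) in _component_table(mask)
        if area in area_range
    ]

    if not survivors:
        return Detection(
            frame_index=frame_index,
            mask=None,
            window_origin=(sx, sy) if prev is not None else _window_bounds((w / 2, h / 2), side, (h, w)),
            window_size=prev.window_size if prev is not None else side,
            centroid=None,
            area=0.0,
            valid=False,
        )

    if prev_centroid is not None:
        def sort_key(item):
            _, _, (cx, cy) = item
            return (np.hypot(cx - prev_centroid[0], cy - prev_centroid[1]), item[0])
    else:
        def sort_key(item):
            return (-item[1], item[0])
    _, area, centroid = sorted(survivors, key=sort_key)[0]

    x0, y0 = _window_bounds(centroid, side, (h, w))
    win = frame[y0 : y0 + side, x0 : x0 + side]
    win_mask = threshold_blue(
        win,
        method=threshold_method,
        fixed_value=fixed_value,
        assume_dark_foreground=assume_dark_foreground,
    )
    return Detection(
        frame_index=frame_index,
        mask=win_mask,
        window_origin=(x0, y0),
        window_size=side,
        centroid=centroid,
        area=area,
        valid=True,
    )


def track_video(
    video,
    area_range: AreaRange,
    frame_step: int = 2,
    window_scale: float = 3.0,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    assume_dark_foreground: bool = True,
) -> list[Detection]:
    """Track the animal through frames ``0, frame_step, 2*frame_step, ...``.

    Each processed frame uses the previous processed frame's detection as
    its tracking prior; with the default step of 2 this halves the work,
    and ``ceil(n_frames / frame_step)`` detections are returned.
    """
    if frame_step < 1:
        raise ValueError("frame_step must be at least 1")
    frames = fio.load_frames(video)
    detections: list[Detection] = []
    prev: Detection | None = None
    for idx in range(0, len(frames), frame_step):
        det = detect_froglet(
            frames[idx],
            area_range,
            prev=prev,
            frame_index=idx,
            window_scale=window_scale,
            threshold_method=threshold_method,
            fixed_value=fixed_value,
            assume_dark_foreground=assume_dark_foreground,
        )
        detections.append(det)
        prev = det if det.valid else (prev if prev is not None else det)
    return detections


def detections_to_dataframe(detections: Sequence[Detection]) -> pd.DataFrame:
    """Per-frame detection table (the ``track`` stage's CSV payload)."""
    rows = []
    for d in detections:
        cx, cy = d.centroid if d.centroid is not None else (np.nan, np.nan)
        rows.append(
            {
                "frame_index": d.frame_index,
                "valid": d.valid,
                "cx": cx,
                "cy": cy,
                "area": d.area,
                "window_x": d.window_origin[0],
                "window_y": d.window_origin[1],
                "window_size": d.window_size,
            }
        )
    return pd.DataFrame(rows)


def save_detections(detections: Sequence[Detection], path: str | Path) -> None:
    detections_to_dataframe(detections).to_csv(path, index=False)
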