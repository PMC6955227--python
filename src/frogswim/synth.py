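"""Synthetic swimming-froglet videos with exact per-frame ground truth.

A post-metamorphic *Xenopus laevis* froglet seen from above is emulated as
a dark elliptical body with four rigid limb segments on a light
background.  Hindlimb angle trajectories are sinusoidal strokes whose
amplitude, mean posture, phase relation and jitter differ by spinal-cord
injury class:

* ``uninjured``   — large, equal-amplitude, in-phase strokes;
* ``hemisected``  — right (lesioned-side) stroke roughly half the left,
  with per-stroke phase resampling so the two feet decorrelate;
* ``transected``  — small, equal, anti-phase wiggles (pelvis rocking seen
  as inverted foot motion).

Every rendered frame carries a sidecar record of the true body centroid,
heading, limb endpoint coordinates and hindfoot angle-pair, so tracking,
pose and feature extraction can all be validated against known truth.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _geometry as geo

__all__ = [
    "ClassLabel",
    "MotionModel",
    "RenderParams",
    "GroundTruthTraces",
    "default_motion_model",
    "generate_traces",
    "render_frame",
    "render_frames",
    "render_video",
    "body_frame_endpoints",
]

LIMB_NAMES = ("fore_right", "fore_left", "hind_right", "hind_left")

# Body-frame directions of the limb attachment points on the body outline.
# Hind anchors sit slightly lateral of the posterior pole, fore anchors
# mirror them toward the anterior.
_HIND_ANCHOR_DEG = 70.0
_FORE_ANCHOR_DEG = 65.0


class ClassLabel(str, enum.Enum):
    """The three spinal-cord damage categories."""

    UNINJURED = "uninjured"
    HEMISECTED = "hemisected"
    TRANSECTED = "transected"

    @classmethod
    def coerce(cls, value: "ClassLabel | str") -> "ClassLabel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ValueError(
                f"unknown class label {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from exc


@dataclass(frozen=True)
class MotionModel:
    """Parametric hindlimb stroke model for one animal.

    Angles are hindfoot angles in degrees (0 = foot lateral, 90 = foot
    straight posterior).  The left trace carries the phase offset and the
    per-stroke phase jitter; 0 offset means in-phase, pi anti-phase.
    """

    amplitude_right: float
    amplitude_left: float
    mean_angle_right: float
    mean_angle_left: float
    phase_offset: float = 0.0
    stroke_frequency: float = 2.0
    angle_noise_sd: float = 0.0
    phase_jitter_sd: float = 0.0
    fore_amplitude: float = 12.0
    fore_mean_angle: float = 42.0

    def __post_init__(self) -> None:
        if self.amplitude_right < 0 or self.amplitude_left < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.stroke_frequency <= 0:
            raise ValueError("stroke_frequency must be positive")
        if self.angle_noise_sd < 0 or self.phase_jitter_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for mean, amp in (
            (self.mean_angle_right, self.amplitude_right),
            (self.mean_angle_left, self.amplitude_left),
        ):
            if mean - amp < 0.0 or mean + amp > 180.0:
                raise ValueError("mean +- amplitude must stay within [0, 180] degrees")


# Class-typical stroke parameters: (amp_R, amp_L, mean_R, mean_L,
# phase_offset, angle_noise_sd, phase_jitter_sd).  Chosen so the derived
# features land in the regions observed per class: in-phase equal strokes
# whose measured range of motion is near 97 degrees for uninjured
# animals, a halved right-side stroke with decorrelated phase for
# hemisected ones, and small anti-phase wiggles with a range near 38
# degrees for transected ones.  (The KDE smoothing in the range feature
# widens the measured arc ~10 degrees beyond twice the amplitude, which
# these amplitudes account for.)
_CLASS_PARAMS: dict[ClassLabel, tuple[float, ...]] = {
    ClassLabel.UNINJURED: (43.0, 43.0, 56.0, 56.0, 0.0, 3.0, 0.08),
    ClassLabel.HEMISECTED: (21.5, 43.0, 35.0, 56.0, 0.0, 3.0, 2.5),
    ClassLabel.TRANSECTED: (14.0, 14.0, 50.0, 50.0, np.pi, 1.5, 0.08),
}


def default_motion_model(label: ClassLabel | str, seed: int) -> MotionModel:
    """Class-typical stroke model with seeded per-animal variation.

    The same ``(label, seed)`` always yields the same model.  Amplitudes
    are scaled by a common factor in [0.92, 1.08], mean postures shifted
    by up to +-4 degrees and the stroke frequency drawn from
    [1.7, 2.3] Hz, emulating inter-animal variability within a class.
    """
    label = ClassLabel.coerce(label)
    amp_r, amp_l, mean_r, mean_l, offset, noise_sd, jitter_sd = _CLASS_PARAMS[label]
    label_key = zlib.crc32(label.value.encode()) & 0xFFFF
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, label_key])
    scale = rng.uniform(0.92, 1.08)
    shift = rng.uniform(-4.0, 4.0)
    freq = rng.uniform(1.7, 2.3)
    return MotionModel(
        amplitude_right=amp_r * scale,
        amplitude_left=amp_l * scale,
        mean_angle_right=mean_r + shift,
        mean_angle_left=mean_l + shift,
        phase_offset=offset,
        stroke_frequency=freq,
        angle_noise_sd=noise_sd,
        phase_jitter_sd=jitter_sd,
    )


@dataclass(frozen=True)
class RenderParams:
    """Geometry and photometry of the rendered scene.

    ``body_axes`` is (axial semi-major, lateral semi-minor) in pixels.
    The background must be brighter than the animal in the blue channel,
    which is what the segmenter thresholds on.
    """

    frame_size: tuple[int, int] = (512, 384)  # (width, height)
    body_axes: tuple[float, float] = (40.0, 22.0)
    limb_length: float = 48.0
    limb_width: float = 7.0
    fore_limb_length: float = 26.0
    fore_limb_width: float = 5.0
    foreground_rgb: tuple[int, int, int] = (60, 50, 40)
    background_rgb: tuple[int, int, int] = (200, 205, 230)
    swim_speed: float = 0.8  # pixels per frame
    fps: float = 60.0
    heading_wobble_deg: float = 3.0
    pixel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rgb[2] <= self.foreground_rgb[2]:
            raise ValueError(
                "background blue intensity must exceed the animal's blue "
                "intensity for blue-channel thresholding to work"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.body_axes[0] <= self.body_axes[1]:
            raise ValueError("the axial semi-axis must exceed the lateral one")

    # -- derived geometry -------------------------------------------------
    def anchor(self, limb: str) -> np.ndarray:
        """Body-frame attachment point of a limb on the body outline."""
        a, b = self.body_axes
        if limb.startswith("hind"):
            ang = np.deg2rad(_HIND_ANCHOR_DEG)
            d = np.array([np.cos(ang), np.sin(ang)])
        else:
            ang = np.deg2rad(_FORE_ANCHOR_DEG)
            d = np.array([np.cos(ang), -np.sin(ang)])
        if limb.endswith("left"):
            d = d * np.array([-1.0, 1.0])
        return d * geo.ellipse_boundary_radius(d, semi_lateral=b, semi_axial=a)

    def limb_segment_length(self, limb: str) -> float:
        return self.limb_length if limb.startswith("hind") else self.fore_limb_length

    def endpoint_radius(self, limb: str, direction: np.ndarray) -> float:
        """Distance from the body centroid to the limb endpoint.

        The limb is a rigid segment of fixed length from its anchor, so
        the endpoint lies where the circle of that radius around the
        anchor meets the ray from the centroid along ``direction``; its
        distance from the centroid therefore varies with the stroke
        angle, while the rendered limb area stays constant.
        """
        a = self.anchor(limb)
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        length = self.limb_segment_length(limb)
        ua = float(u @ a)
        disc = ua**2 - float(a @ a) + length**2
        if disc < 0:
            raise ValueError("limb too short to reach the stroke ray")
        return ua + float(np.sqrt(disc))

    def reach(self) -> float:
        """Maximum extent of any animal pixel from the body centroid."""
        r = max(
            np.linalg.norm(self.anchor("hind_right")) + self.limb_length,
            np.linalg.norm(self.anchor("fore_right")) + self.fore_limb_length,
        )
        return float(r) + 0.5 * max(self.limb_width, self.fore_limb_width)


@dataclass
class GroundTruthTraces:
    """Per-frame ground truth of a synthetic swim.

    ``frames`` has one row per frame with columns: ``frame_index``,
    ``body_cx``/``body_cy`` (ellipse center), ``heading_deg``,
    ``alpha_right``/``alpha_left`` (hindfoot angles, degrees in
    [0, 180)), ``alpha_fore_right``/``alpha_fore_left`` and full-frame
    endpoint coordinates ``<limb>_x``/``<limb>_y`` for the four limbs.
    ``render_video`` appends ``mask_cx``/``mask_cy``, the centroid of the
    whole rendered silhouette (body plus limbs), which is what a
    segmentation stage actually measures.
    """

    frames: pd.DataFrame
    fps: float
    params: RenderParams = field(default_factory=RenderParams)

    def __len__(self) -> int:
        return len(self.frames)

    def to_csv(self, path: str | Path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float, params: RenderParams | None = None) -> "GroundTruthTraces":
        return cls(pd.read_csv(path), fps=fps, params=params or RenderParams())


def _clip_angles(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, np.nextafter(180.0, 0.0))


def generate_traces(
    model: MotionModel,
    n_frames: int,
    fps: float | None = None,
    seed: int = 0,
    params: RenderParams | None = None,
) -> GroundTruthTraces:
    """Simulate angle trajectories and the body path for ``n_frames``.

    The right hindfoot follows ``mean_R + A_R sin(2 pi f t)`` plus white
    angle noise; the left adds the phase offset and a per-stroke phase
    jitter (one Gaussian draw per stroke cycle, giving decorrelated feet
    when the jitter SD is large).  Angles are clipped to [0, 180).  The
    body drifts forward at constant speed while the heading wobbles
    sinusoidally at the stroke frequency.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")
    params = params or RenderParams()
    fps = float(fps if fps is not None else params.fps)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    t = np.arange(n_frames) / fps
    w = 2.0 * np.pi * model.stroke_frequency

    stroke_idx = np.floor(model.stroke_frequency * t).astype(int)
    n_strokes = int(stroke_idx.max()) + 1
    jitter = (
        rng.normal(0.0, model.phase_jitter_sd, size=n_strokes)[stroke_idx]
        if model.phase_jitter_sd > 0
        else np.zeros(n_frames)
    )

    noise_r = rng.normal(0.0, model.angle_noise_sd, n_frames) if model.angle_noise_sd else 0.0
    noise_l = rng.normal(0.0, model.angle_noise_sd, n_frames) if model.angle_noise_sd else 0.0
    alpha_r = _clip_angles(model.mean_angle_right + model.amplitude_right * np.sin(w * t) + noise_r)
    alpha_l = _clip_angles(
        model.mean_angle_left
        + model.amplitude_left * np.sin(w * t + model.phase_offset + jitter)
        + noise_l
    )
    fore_noise = rng.normal(0.0, 1.0, (2, n_frames))
    alpha_fr = _clip_angles(model.fore_mean_angle + model.fore_amplitude * np.sin(w * t) + fore_noise[0])
    alpha_fl = _clip_angles(model.fore_mean_angle + model.fore_amplitude * np.sin(w * t) + fore_noise[1])

    # Forward locomotion: constant speed along a gently wobbling heading.
    heading = params.heading_wobble_deg * np.sin(w * t + rng.uniform(0, 2 * np.pi))
    w_px, h_px = params.frame_size
    margin = params.reach() + 8.0
    start = np.array([w_px / 2.0, h_px - margin])
    phi = np.deg2rad(heading)
    head_dir = np.stack([np.sin(phi), -np.cos(phi)], axis=1)
    pos = start + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(params.swim_speed * head_dir[:-1], axis=0)]
    )

    rows: dict[str, np.ndarray] = {
        "frame_index": np.arange(n_frames),
        "body_cx": pos[:, 0],
        "body_cy": pos[:, 1],
        "heading_deg": heading,
        "alpha_right": alpha_r,
        "alpha_left": alpha_l,
        "alpha_fore_right": alpha_fr,
        "alpha_fore_left": alpha_fl,
    }

    angles = {
        "hind_right": ("right", alpha_r, False),
        "hind_left": ("left", alpha_l, False),
        "fore_right": ("right", alpha_fr, True),
        "fore_left": ("left", alpha_fl, True),
    }
    for limb, (side, alphas, is_fore) in angles.items():
        units = np.array([geo.unit_from_angle(a, side) for a in alphas])
        if is_fore:
            units[:, 1] = -units[:, 1]  # forelimbs sweep toward the anterior
        radii = np.array([params.endpoint_radius(limb, u) for u in units])
        pts = np.array(
            [
                geo.body_to_image(r * u, c, h)
                for r, u, c, h in zip(radii, units, pos, heading)
            ]
        )
        rows[f"{limb}_x"] = pts[:, 0]
        rows[f"{limb}_y"] = pts[:, 1]

    return GroundTruthTraces(pd.DataFrame(rows), fps=fps, params=params)


def body_frame_endpoints(traces: GroundTruthTraces, limb: str) -> np.ndarray:
    """Ground-truth endpoint positions of ``limb`` in the body frame."""
    df = traces.frames
    pts = df[[f"{limb}_x", f"{limb}_y"]].to_numpy()
    cents = df[["body_cx", "body_cy"]].to_numpy()
    return np.array(
        [geo.image_to_body(p, c, h) for p, c, h in zip(pts, cents, df["heading_deg"])]
    )


def render_frame(row: pd.Series, params: RenderParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one RGB frame from a ground-truth record."""
    w, h = params.frame_size
    center = np.array([row["body_cx"], row["body_cy"]])
    a, b = params.body_axes
    mask = np.zeros((h, w), dtype=bool)
    geo.fill_ellipse(mask, center, semi_axial=a, semi_lateral=b, heading_deg=row["heading_deg"])
    for limb in LIMB_NAMES:
        endpoint = np.array([row[f"{limb}_x"], row[f"{limb}_y"]])
        radius = 0.5 * (params.limb_width if limb.startswith("hind") else params.fore_limb_width)
        if not (
            radius < endpoint[0] < w - radius and radius < endpoint[1] < h - radius
        ):
            raise ValueError(
                f"limb geometry exits the frame at frame {int(row['frame_index'])} "
                f"({limb} endpoint at {endpoint.round(1)})"
            )
        anchor = geo.body_to_image(params.anchor(limb), center, row["heading_deg"])
        geo.fill_capsule(mask, anchor, endpoint, radius)

    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = np.asarray(params.background_rgb, dtype=np.uint8)
    frame[mask] = np.asarray(params.foreground_rgb, dtype=np.uint8)
    if params.pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        noisy = frame.astype(float) + rng.normal(0.0, params.pixel_noise_sd, frame.shape)
        frame = np.clip(noisy, 0, 255).astype(np.uint8)
    return frame


def render_frames(traces: GroundTruthTraces, params: RenderParams | None = None, seed: int = 0):
    """Yield rendered RGB frames for every record in ``traces``."""
    params = params or traces.params
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    for _, row in traces.frames.iterrows():
        yield render_frame(row, params, rng)


def render_video(
    traces: GroundTruthTraces,
    params: RenderParams | None = None,
    out_path: str | Path | None = None,
    seed: int = 0,
) -> tuple[list[np.ndarray], GroundTruthTraces]:
    """Render all frames and (optionally) write them plus the sidecar table.

    Returns the frame list and a copy of ``traces`` augmented with the
    measured silhouette centroid (``mask_cx``/``mask_cy``).  When
    ``out_path`` is given, frames are written there: a directory receives
    numbered PNGs (the bit-exact default), while a ``.mp4``/``.avi``
    suffix is passed to :mod:`imageio` (requires an ffmpeg plugin).  The
    ground-truth table is written alongside as ``ground_truth.csv``.
    """
    if len(traces) == 0:
        raise ValueError("traces are empty")
    params = params or traces.params
    frames: list[np.ndarray] = []
    mask_cx, mask_cy = [], []
    fg_blue = params.foreground_rgb[2]
    bg_blue = params.background_rgb[2]
    thresh = 0.5 * (fg_blue + bg_blue)
    for frame in render_frames(traces, params, seed=seed):
        frames.append(frame)
        m = frame[:, :, 2] < thresh
        ys, xs = np.nonzero(m)
        mask_cx.append(xs.mean())
        mask_cy.append(ys.mean())

    df = traces.frames.copy()
    df["mask_cx"] = mask_cx
    df["mask_cy"] = mask_cy
    out_traces = GroundTruthTraces(df, traces.fps, params)

    if out_path is not None:
        out_path = Path(out_path)
        from . import io as fio

        if out_path.suffix.lower() in {".mp4", ".avi", ".mov", ".mkv"}:
            fio.write_video_file(out_path, frames, fps=traces.fps)
            sidecar = out_path.with_name(out_path.stem + "_ground_truth.csv")
        else:
            fio.write_frame_dir(out_path, frames)
            sidecar = out_path / "ground_truth.csv"
        out_traces.to_csv(sidecar)
    return frames, out_traces
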