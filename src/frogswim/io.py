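"""Reading and writing videos, frame directories and stage tables.

A "video" anywhere in this package is any of:

* a directory of numbered image frames (``frame_000000.png``, ...),
* a video container file readable by :mod:`imageio` (requires the
  appropriate plugin, e.g. ffmpeg for MP4/AVI),
* an in-memory sequence of ``(H, W, 3)`` uint8 arrays.

Frame directories are the lossless default produced by the synthetic
renderer; they keep thresholding bit-exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["load_frames", "n_frames", "write_frame_dir", "write_video_file"]

_FRAME_GLOB = "frame_*.png"


def _is_frame_sequence(video) -> bool:
    return not isinstance(video, (str, Path))


def load_frames(video) -> list[np.ndarray]:
    """Materialize a video (path or sequence) as a list of RGB frames."""
    if _is_frame_sequence(video):
        return [np.asarray(f) for f in video]
    path = Path(video)
    if path.is_dir():
        files = sorted(path.glob(_FRAME_GLOB)) or sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg"}
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        return [iio.imread(f) for f in files]
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return [np.asarray(f) for f in iio.imiter(path)]
    except Exception as exc:  # pragma: no cover - depends on plugins present
        raise OSError(
            f"could not read video {path}; for container formats an imageio "
            "ffmpeg plugin is required (frame directories always work)"
        ) from exc


def n_frames(video) -> int:
    if _is_frame_sequence(video):
        return len(video)
    path = Path(video)
    if path.is_dir():
        return len(sorted(path.glob(_FRAME_GLOB)))
    return len(load_frames(video))


def write_frame_dir(path: str | Path, frames: Sequence[np.ndarray]) -> Path:
    """Write frames as numbered PNGs; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(path / f"frame_{i:06d}.png", np.asarray(frame, dtype=np.uint8))
    return path


def write_video_file(path: str | Path, frames: Iterable[np.ndarray], fps: float) -> Path:
    """Write a video container file (needs an imageio ffmpeg plugin)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iio.imwrite(path, [np.asarray(f, dtype=np.uint8) for f in frames], fps=fps)
    except Exception as exc:  # pragma: no cover - depends on plugins present
        raise OSError(
            f"could not write {path}: container output requires an imageio "
            "ffmpeg plugin; use a frame directory for lossless output"
        ) from exc
    return path
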