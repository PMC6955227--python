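"""Shared planar geometry helpers.

Coordinate conventions used across the package
----------------------------------------------
Image coordinates are ``(x, y)`` with ``x`` the column index (rightward)
and ``y`` the row index (downward), matching how frames are stored as
``frame[y, x]`` arrays.

The *body frame* of a dorsally viewed, head-up animal is defined as

* ``+x_body`` — toward the animal's right side,
* ``+y_body`` — toward the posterior (tail/pelvis).

With the head pointing up in the image (``-y``), the animal's right side
coincides with the image's right side, so the canonical body frame is the
image frame translated to the body centroid.

``heading_deg`` is the body heading: 0 means the head points straight up
in the image; positive headings rotate the animal in the direction that
maps ``+x`` onto ``+y`` (visually clockwise on screen).

Hindfoot angles follow one convention everywhere: the angle at the vertex
(centroid) between the lateral ray of that side and the vector to the
foot, sweeping toward the posterior, in degrees within [0, 180).  A foot
pointing straight sideways is at 0 deg, straight back is at 90 deg, and a
mirror-symmetric posture gives identical right and left angles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_matrix",
    "body_to_image",
    "image_to_body",
    "ellipse_boundary_radius",
    "fill_ellipse",
    "fill_capsule",
    "unit_from_angle",
    "angle_from_offset",
]


def rotation_matrix(heading_deg: float) -> np.ndarray:
    """2x2 matrix mapping body-frame vectors to image vectors."""
    phi = np.deg2rad(heading_deg)
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])


def body_to_image(points: np.ndarray, centroid: np.ndarray, heading_deg: float) -> np.ndarray:
    """Map body-frame ``(x, y)`` points to image coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ rotation_matrix(heading_deg).T + np.asarray(centroid, dtype=float)
    return out if np.asarray(points).ndim > 1 else out[0]


def image_to_body(points: np.ndarray, centroid: np.ndarray, heading_deg: float) -> np.ndarray:
    """Inverse of :func:`body_to_image`."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(centroid, dtype=float)
    out = pts @ rotation_matrix(heading_deg)
    return out if np.asarray(points).ndim > 1 else out[0]


def unit_from_angle(alpha_deg: float, side: str) -> np.ndarray:
    """Body-frame unit vector of a hindfoot at angle ``alpha_deg``.

    ``side`` is ``"right"`` or ``"left"``; the angle sweeps from the
    lateral ray of that side toward the posterior.
    """
    a = np.deg2rad(alpha_deg)
    x = np.cos(a)
    if side == "left":
        x = -x
    elif side != "right":
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    return np.array([x, np.sin(a)])


def angle_from_offset(dx: float, dy: float, side: str) -> float:
    """Foot angle in degrees within [0, 180) from a body-frame offset.

    The inverse of :func:`unit_from_angle`; offsets slightly anterior of
    the lateral ray are clamped into the admissible range.
    """
    if side == "left":
        dx = -dx
    elif side != "right":
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    ang = np.degrees(np.arctan2(dy, dx))
    if ang < 0.0:
        # anterior of horizontal: clamp to the nearer end of [0, 180)
        ang = 0.0 if ang > -90.0 else 180.0
    return float(min(ang, np.nextafter(180.0, 0.0)))


def ellipse_boundary_radius(direction: np.ndarray, semi_lateral: float, semi_axial: float) -> float:
    """Distance from the ellipse center to its boundary along ``direction``.

    ``direction`` is a body-frame vector; the ellipse has semi-axis
    ``semi_lateral`` along ``x_body`` and ``semi_axial`` along ``y_body``.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return 1.0 / np.hypot(d[0] / semi_lateral, d[1] / semi_axial)


def _local_grid(shape: tuple[int, int], center: np.ndarray, radius: float):
    """Index window and pixel-center coordinate grids around ``center``."""
    h, w = shape
    x0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    x1 = min(int(np.ceil(center[0] + radius)) + 2, w)
    y0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    y1 = min(int(np.ceil(center[1] + radius)) + 2, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), xs.astype(float), ys.astype(float)


def fill_ellipse(
    canvas: np.ndarray,
    center: np.ndarray,
    semi_axial: float,
    semi_lateral: float,
    heading_deg: float,
) -> None:
    """Rasterize a filled ellipse into a boolean ``canvas`` in place.

    The major (axial) semi-axis runs along the body axis given by
    ``heading_deg``; pixel centers inside the ellipse are set True.
    """
    center = np.asarray(center, dtype=float)
    window, xs, ys = _local_grid(canvas.shape, center, max(semi_axial, semi_lateral))
    dx, dy = xs - center[0], ys - center[1]
    phi = np.deg2rad(heading_deg)
    axial = -dx * np.sin(phi) + dy * np.cos(phi)  # component along head->tail axis
    lateral = dx * np.cos(phi) + dy * np.sin(phi)
    inside = (axial / semi_axial) ** 2 + (lateral / semi_lateral) ** 2 <= 1.0
    canvas[window] |= inside


def fill_capsule(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Rasterize a thick line segment with round caps into ``canvas``."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    mid = 0.5 * (p0 + p1)
    reach = 0.5 * np.linalg.norm(p1 - p0) + radius
    window, xs, ys = _local_grid(canvas.shape, mid, reach)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    dx, dy = xs - p0[0], ys - p0[1]
    if seg_len2 == 0.0:
        dist2 = dx**2 + dy**2
    else:
        t = np.clip((dx * seg[0] + dy * seg[1]) / seg_len2, 0.0, 1.0)
        dist2 = (dx - t * seg[0]) ** 2 + (dy - t * seg[1]) ** 2
    canvas[window] |= dist2 <= radius**2
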