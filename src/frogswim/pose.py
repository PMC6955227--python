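"""Head-up orientation and limb-endpoint detection on body masks.

Per frame, the binary mask from the tracker is processed as follows:

1. *Orientation* — the mask is virtually eroded until the limbs vanish,
   leaving the elliptical body, whose principal axis gives the body
   orientation (limbs would otherwise bias the axis).
2. *Normalization* — the mask is rotated so the body axis is vertical;
   if the top half then holds more foreground pixels than the bottom
   half, the mask is rotated a further 180 degrees.  The posterior half
   (hindlimbs plus pelvis) is the pixel-heavier half and must end up at
   the bottom, i.e. the animal "looks up".
3. *Limb extraction* — the limbs are the difference between the mask and
   its morphologically opened body; dilating limbs and body and
   intersecting them yields the joint zones where limbs attach.
4. *Endpoints* — the morphological skeleton of the limb mask is
   computed; skeleton pixels with exactly one 8-connected skeleton
   neighbor are the candidate hands/feet.
5. *Assignment* — each joint zone is assigned to one of four quadrants
   around the center of gravity; the limb endpoint is the candidate in
   the same limb component furthest from its joint.  (At stroke extremes
   a foot can cross the body midline, and crossed synchronized feet can
   even merge into one component — the furthest-from-joint rule resolves
   both cases, which a naive partition of endpoints by quadrant cannot.)

The hindfoot angle-pair ``(alpha_R, alpha_L)`` is then measured at the
center of gravity of the limb-free body, in the convention of
:mod:`frogswim._geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from ._geometry import angle_from_offset
from .kinematics import AnglePair
from .segment import Detection

__all__ = [
    "Pose",
    "PoseError",
    "estimate_orientation",
    "normalize_orientation",
    "extract_limbs",
    "skeleton_endpoints",
    "assign_limbs",
    "compute_angle_pair",
    "estimate_pose",
    "poses_to_dataframe",
    "default_erosion_radius",
]

LIMB_NAMES = ("fore_right", "fore_left", "hind_right", "hind_left")

# quadrant of each limb in the oriented (head-up) frame:
# (sign of x - cx, sign of y - cy); posterior is +y
_LIMB_QUADRANT = {
    "fore_right": (1, -1),
    "fore_left": (-1, -1),
    "hind_right": (1, 1),
    "hind_left": (-1, 1),
}


class PoseError(ValueError):
    """The mask does not support a pose estimate (empty, degenerate...)."""


@dataclass
class Pose:
    """Per-frame body pose in the oriented (head-up) window.

    ``centroid`` is the center of gravity of the limb-free body;
    ``orientation`` the original body-axis angle versus the horizontal in
    (-90, 90]; ``limb_endpoints`` maps limb names to (x, y) in the
    oriented window; ``joint_zones`` maps limb names to joint-zone pixel
    centroids.  Limbs without a detected endpoint have
    ``valid_limbs[name] == False`` and no entry in ``limb_endpoints``.
    """

    frame_index: int
    centroid: tuple[float, float]
    orientation: float
    limb_endpoints: dict[str, tuple[float, float]] = field(default_factory=dict)
    joint_zones: dict[str, tuple[float, float]] = field(default_factory=dict)
    valid_limbs: dict[str, bool] = field(default_factory=dict)

    def endpoint_offset(self, limb: str) -> tuple[float, float] | None:
        """Endpoint relative to the centroid, or None if invalid."""
        if not self.valid_limbs.get(limb, False):
            return None
        x, y = self.limb_endpoints[limb]
        return (x - self.centroid[0], y - self.centroid[1])


def default_erosion_radius(calibration_area: float, factor: float = 0.25) -> int:
    """Erosion radius that removes limbs but preserves the body.

    A quarter of the equivalent-disc radius of the calibrated animal
    area: comfortably wider than a limb, comfortably narrower than the
    body's semi-minor axis.
    """
    return max(int(round(factor * np.sqrt(calibration_area / np.pi))), 2)


def _body_open(mask: np.ndarray, erosion_radius: int) -> np.ndarray:
    """Limb-free body: morphological opening with a disc element.

    Erosion alone would also shave a rim off the body, so the subtraction
    limb = mask - body is computed against the opened (eroded then
    re-dilated) mask, which restores the body outline while the thin
    limbs stay removed.
    """
    return ndimage.binary_opening(mask, structure=morphology.disk(erosion_radius))


def estimate_orientation(mask: np.ndarray, erosion_radius: int) -> float:
    """Body-axis angle versus the horizontal, degrees in (-90, 90].

    The mask is virtually eroded to eliminate the limbs and the principal
    axis of the remaining body region is measured.  A region without a
    clear principal axis (axis ratio below 1.2, e.g. a circle) raises
    :class:`PoseError`.
    """
    body = ndimage.binary_erosion(np.asarray(mask, bool), structure=morphology.disk(erosion_radius))
    if not body.any():
        raise PoseError("mask is empty after erosion; erosion_radius too large?")
    region = max(measure.regionprops(measure.label(body)), key=lambda r: r.area)
    if region.axis_minor_length == 0 or region.axis_major_length / region.axis_minor_length < 1.2:
        raise PoseError("degenerate orientation: body region has no clear principal axis")
    # regionprops: angle between the row axis and the major axis, so a
    # vertical major axis is 0; convert to angle versus the horizontal.
    vs_horizontal = 90.0 - np.degrees(region.orientation)
    if vs_horizontal > 90.0:
        vs_horizontal -= 180.0
    return float(vs_horizontal)


def _half_counts(mask: np.ndarray, split_row: float) -> tuple[int, int]:
    rows = np.nonzero(mask)[0]
    return int((rows < split_row).sum()), int((rows > split_row).sum())


def normalize_orientation(
    mask: np.ndarray, angle: float, erosion_radius: int | None = None
) -> tuple[np.ndarray, float]:
    """Rotate the mask head-up; returns (oriented mask, applied rotation).

    The mask is rotated so the body axis given by ``angle`` (degrees
    versus the horizontal) becomes vertical, then flipped 180 degrees if
    the top half (above the body centroid row) holds strictly more
    foreground pixels than the bottom half — the posterior half is the
    heavier one and belongs at the bottom.  Ties do not flip.  The
    returned rotation is the total applied angle in degrees.
    """
    if not np.isfinite(angle):
        raise ValueError("orientation angle must be finite")
    mask = np.asarray(mask, bool)
    rot = angle - 90.0
    # bilinear interpolation of the indicator plus a 0.5 threshold keeps
    # rotated limb outlines much smoother than nearest-neighbor sampling
    oriented = ndimage.rotate(mask.astype(float), rot, reshape=True, order=1) >= 0.5
    if erosion_radius is not None:
        body = _body_open(oriented, erosion_radius)
        ref = body if body.any() else oriented
    else:
        ref = oriented
    split = ndimage.center_of_mass(ref)[0]
    top, bottom = _half_counts(oriented, split)
    if top > bottom:
        oriented = oriented[::-1, ::-1]
        rot += 180.0
    return oriented, rot


def extract_limbs(
    oriented_mask: np.ndarray, erosion_radius: int, dilation_radius: int = 2, min_limb_area: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Split an oriented mask into limbs and joint zones.

    Subtracting the opened body from the original mask extracts the
    limbs; dilating both limbs and body and intersecting gives the joint
    zones where they attach.  Components smaller than ``min_limb_area``
    pixels are discarded as rasterization debris.  Raises
    :class:`PoseError` if no limb component remains.
    """
    oriented_mask = np.asarray(oriented_mask, bool)
    if not oriented_mask.any():
        raise PoseError("oriented mask is empty")
    body = _body_open(oriented_mask, erosion_radius)
    limb_mask = oriented_mask & ~body
    limb_mask = _drop_small_components(limb_mask, min_limb_area)
    if not limb_mask.any():
        raise PoseError("no limb components found (limbless mask?)")
    selem = morphology.disk(dilation_radius)
    joints = ndimage.binary_dilation(limb_mask, structure=selem) & ndimage.binary_dilation(
        body, structure=selem
    )
    return limb_mask, joints


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[labels]


_NEIGHBOR_KERNEL = np.ones((3, 3), dtype=int)


def skeleton_endpoints(limb_mask: np.ndarray) -> np.ndarray:
    """Endpoints of the morphological skeleton, as an (n, 2) array of (x, y).

    An endpoint is a skeleton pixel with exactly one 8-connected skeleton
    neighbor — a candidate hand or foot tip.
    """
    limb_mask = np.asarray(limb_mask, bool)
    if not limb_mask.any():
        raise PoseError("limb mask is empty")
    skel = morphology.skeletonize(limb_mask)
    neighbors = ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant") - skel
    ys, xs = np.nonzero(skel & (neighbors == 1))
    return np.column_stack([xs, ys]).astype(float)


def _quadrant(point: tuple[float, float], centroid: tuple[float, float]) -> tuple[int, int]:
    return (1 if point[0] >= centroid[0] else -1, 1 if point[1] >= centroid[1] else -1)


# Anatomical prior for the limb attachment sites, as directions from the
# body center in the oriented frame: hips sit posterolateral (~70 degrees
# below the lateral ray), shoulders anterolateral.  Used only as stable
# reference points for the furthest-from-joint rule.
_ATTACH_DEG = {"hind": 70.0, "fore": 65.0}


def _attachment_refs(body_mask: np.ndarray) -> dict[str, tuple[float, float]] | None:
    """Hip/shoulder reference points estimated from the body ellipse."""
    props = measure.regionprops(measure.label(np.asarray(body_mask, bool)))
    if not props:
        return None
    region = max(props, key=lambda r: r.area)
    cy, cx = region.centroid
    a = region.axis_major_length / 2.0
    b = region.axis_minor_length / 2.0
    if a == 0 or b == 0:
        return None
    refs = {}
    for name in LIMB_NAMES:
        ang = np.deg2rad(_ATTACH_DEG[name.split("_")[0]])
        dx, dy = np.cos(ang), np.sin(ang)
        if name.endswith("left"):
            dx = -dx
        if name.startswith("fore"):
            dy = -dy
        r = 1.0 / np.hypot(dx / b, dy / a)
        refs[name] = (cx + r * dx, cy + r * dy)
    return refs


def assign_limbs(
    endpoints: np.ndarray,
    joint_zones: np.ndarray,
    centroid: tuple[float, float],
    limb_mask: np.ndarray | None = None,
    body_mask: np.ndarray | None = None,
    frame_index: int = 0,
    orientation: float = 90.0,
) -> Pose:
    """Assign skeleton endpoints to the four limbs.

    Each limb lives in one quadrant around the center of gravity, and the
    chosen endpoint is the furthest candidate from the limb's joint.
    When ``limb_mask`` and ``body_mask`` are given, the candidates are
    the endpoints of the limb component attached at that limb's hip or
    shoulder (estimated from the body ellipse), and the furthest-from-
    joint rule is applied within the component.  This stays correct when
    a foot sweeps across the body midline, and even when two crossed
    limbs merge into one component: a crossed foot is *further* from its
    own hip than the other foot, so the rule recovers the right identity
    where a naive partition of endpoint positions by quadrant cannot.  If
    two limbs elect the same endpoint (nearly coincident feet), the limb
    for which it is further keeps it and the other takes its next
    candidate.  Without the masks, endpoints are simply partitioned by
    their own quadrant and measured against that quadrant's joint-zone
    centroid.  Limbs without any candidate are flagged invalid.
    """
    endpoints = (
        np.atleast_2d(np.asarray(endpoints, dtype=float)) if np.size(endpoints) else np.empty((0, 2))
    )
    pose = Pose(frame_index=frame_index, centroid=tuple(centroid), orientation=orientation)
    pose.valid_limbs = {name: False for name in LIMB_NAMES}

    # joint-zone centroids per quadrant (reported in the pose; reference
    # points for the fallback path)
    quadrant_joints: dict[tuple[int, int], tuple[float, float]] = {}
    joint_labels = measure.label(np.asarray(joint_zones, bool), connectivity=2)
    best_area: dict[tuple[int, int], float] = {}
    for region in measure.regionprops(joint_labels):
        cy, cx = region.centroid
        quad = _quadrant((cx, cy), centroid)
        if region.area > best_area.get(quad, 0):
            best_area[quad] = region.area
            quadrant_joints[quad] = (float(cx), float(cy))
    quad_to_name = {q: n for n, q in _LIMB_QUADRANT.items()}
    for quad, joint_xy in quadrant_joints.items():
        pose.joint_zones[quad_to_name[quad]] = joint_xy

    # endpoints inside a joint zone are where a limb was cut off at the
    # body, not hands or feet; they are never candidates
    exclusion = ndimage.binary_dilation(
        np.asarray(joint_zones, bool), structure=morphology.disk(2)
    )

    def is_stub(p) -> bool:
        x = int(round(np.clip(p[0], 0, exclusion.shape[1] - 1)))
        y = int(round(np.clip(p[1], 0, exclusion.shape[0] - 1)))
        return bool(exclusion[y, x])

    endpoints = np.asarray([p for p in endpoints if not is_stub(p)]) if len(endpoints) else endpoints
    if endpoints.size == 0:
        endpoints = np.empty((0, 2))

    refs = _attachment_refs(body_mask) if body_mask is not None else None
    limb_labels = None
    if limb_mask is not None and refs is not None:
        padded = ndimage.binary_dilation(np.asarray(limb_mask, bool), structure=morphology.disk(2))
        limb_labels = measure.label(padded, connectivity=2)

    def label_at(point) -> int:
        x = int(round(np.clip(point[0], 0, limb_labels.shape[1] - 1)))
        y = int(round(np.clip(point[1], 0, limb_labels.shape[0] - 1)))
        return int(limb_labels[y, x])

    def component_near(ref, radius: int = 7) -> int:
        """Limb component attached near a reference point (0 if none)."""
        h, w = limb_labels.shape
        x0, y0 = int(round(ref[0])), int(round(ref[1]))
        votes: dict[int, int] = {}
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dx * dx + dy * dy > radius * radius:
                    continue
                x, y = x0 + dx, y0 + dy
                if 0 <= x < w and 0 <= y < h and limb_labels[y, x]:
                    votes[limb_labels[y, x]] = votes.get(limb_labels[y, x], 0) + 1
        return max(votes, key=votes.get) if votes else 0

    ranked: dict[str, list] = {}
    for name in LIMB_NAMES:
        if limb_labels is not None:
            ref = refs[name]
            comp = component_near(ref)
            pool = [p for p in endpoints if comp and label_at(p) == comp]
        else:
            quad = _LIMB_QUADRANT[name]
            ref = quadrant_joints.get(quad, tuple(centroid))
            pool = [p for p in endpoints if _quadrant(p, centroid) == quad]
        ranked[name] = sorted(pool, key=lambda p: -np.hypot(p[0] - ref[0], p[1] - ref[1]))
        ranked[name] = [(p, float(np.hypot(p[0] - ref[0], p[1] - ref[1]))) for p in ranked[name]]

    chosen: dict[str, tuple[float, float] | None] = {
        name: (tuple(ranked[name][0][0]) if ranked[name] else None) for name in LIMB_NAMES
    }

    # When the two limbs of a girdle elect the same endpoint (merged
    # crossed limbs), re-match by the bilateral-symmetry prior: of all
    # ways to give the pair two distinct endpoints, the anatomically
    # plausible one makes the two joint-to-endpoint distances most
    # similar, because the limbs have equal length.  With a single
    # candidate (fused tips) the nearer limb keeps it and the other is
    # invalid for this frame.
    for right_name, left_name in (("hind_right", "hind_left"), ("fore_right", "fore_left")):
        cr, cl = chosen[right_name], chosen[left_name]
        if cr is None or cl is None or cr != cl:
            continue
        pool = {tuple(p): d for p, d in ranked[right_name]}
        pool_l = {tuple(p): d for p, d in ranked[left_name]}
        common = [p for p in pool if p in pool_l]
        if len(common) >= 2:
            best_pair = min(
                (
                    (abs(pool[pr] - pool_l[pl]), -(pool[pr] + pool_l[pl]), pr, pl)
                    for pr in common
                    for pl in common
                    if pr != pl
                ),
            )
            chosen[right_name], chosen[left_name] = best_pair[2], best_pair[3]
        else:
            if pool.get(cr, 0.0) <= pool_l.get(cl, 0.0):
                chosen[left_name] = None
            else:
                chosen[right_name] = None

    for name in LIMB_NAMES:
        pt = chosen[name]
        if pt is not None:
            pose.limb_endpoints[name] = (float(pt[0]), float(pt[1]))
            pose.valid_limbs[name] = True
    return pose


def compute_angle_pair(pose: Pose) -> AnglePair:
    """Hindfoot angle-pair of a pose, degrees in [0, 180).

    Each angle is measured at the center of gravity between the lateral
    ray of that side and the vector to the hindfoot, sweeping toward the
    posterior, so a mirror-symmetric posture yields equal angles.  If
    either hindfoot is undetected the pair is flagged invalid.
    """
    right = pose.endpoint_offset("hind_right")
    left = pose.endpoint_offset("hind_left")
    if right is None or left is None:
        return AnglePair(np.nan, np.nan, frame_index=pose.frame_index, valid=False)
    return AnglePair(
        alpha_right=angle_from_offset(right[0], right[1], "right"),
        alpha_left=angle_from_offset(left[0], left[1], "left"),
        frame_index=pose.frame_index,
        valid=True,
    )


def estimate_pose(
    detection: Detection | np.ndarray,
    erosion_radius: int,
    dilation_radius: int = 2,
    min_limb_area: int = 8,
    frame_index: int | None = None,
) -> Pose:
    """Full per-frame pose estimate from a tracked mask.

    Orchestrates orientation, head-up normalization, limb extraction,
    skeleton endpoints and quadrant assignment.  Raises
    :class:`PoseError` on masks that cannot be posed (empty, limbless,
    degenerate orientation).
    """
    if isinstance(detection, Detection):
        if not detection.valid or detection.mask is None:
            raise PoseError(f"frame {detection.frame_index}: no valid detection")
        mask = detection.mask
        if frame_index is None:
            frame_index = detection.frame_index
    else:
        mask = np.asarray(detection, bool)
        frame_index = frame_index or 0

    angle = estimate_orientation(mask, erosion_radius)
    oriented, _ = normalize_orientation(mask, angle, erosion_radius=erosion_radius)
    body = _body_open(oriented, erosion_radius)
    if not body.any():
        raise PoseError("body vanished after opening")
    cy, cx = ndimage.center_of_mass(body)
    centroid = (float(cx), float(cy))
    limb_mask, joints = extract_limbs(oriented, erosion_radius, dilation_radius, min_limb_area)
    endpoints = skeleton_endpoints(limb_mask)
    return assign_limbs(
        endpoints,
        joints,
        centroid,
        limb_mask=limb_mask,
        body_mask=body,
        frame_index=frame_index,
        orientation=angle,
    )


def poses_to_dataframe(poses: Sequence[Pose]) -> pd.DataFrame:
    """Per-frame pose table (the ``pose`` stage's CSV payload)."""
    rows = []
    for p in poses:
        row: dict = {
            "frame_index": p.frame_index,
            "orientation_deg": p.orientation,
            "centroid_x": p.centroid[0],
            "centroid_y": p.centroid[1],
        }
        for name in LIMB_NAMES:
            valid = p.valid_limbs.get(name, False)
            x, y = p.limb_endpoints.get(name, (np.nan, np.nan))
            row[f"{name}_x"], row[f"{name}_y"], row[f"{name}_valid"] = x, y, valid
        pair = compute_angle_pair(p)
        row["alpha_right"], row["alpha_left"], row["pair_valid"] = (
            pair.alpha_right,
            pair.alpha_left,
            pair.valid,
        )
        rows.append(row)
    return pd.DataFrame(rows)
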