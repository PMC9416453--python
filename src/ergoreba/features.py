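"""Joint-line distance features and body-part stream splitting.

Each joint is described by its 3D coordinates concatenated with its
perpendicular distances to the lines through every unordered pair of the
remaining 13 joints (C(13,2) = 78 distances), giving an 81-dimensional
feature per joint. The distances are rigid-motion invariant; only the raw
coordinates change under rotation. Line distances use Heron's formula
(twice the triangle area over the base) with a clamp for tiny negative
radicands from rounding.

The 14 per-joint features are then routed into three overlapping body-part
streams mirroring how an ergonomist scores a posture: trunk, arms and legs,
with Head and Neck shared by all three as postural context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import (JOINT_ORDER, N_JOINTS, JointId, SchemaError,
                       SkeletonFrame, SkeletonSequence, center_to_neck)

__all__ = [
    "joint_line_distance",
    "frame_features",
    "split_streams",
    "sequence_stream_features",
    "JointFeature",
    "StreamFeatures",
    "TRUNK_JOINTS",
    "ARMS_JOINTS",
    "LEGS_JOINTS",
    "FEATURES_PER_JOINT",
    "STREAM_DIMS",
]

#: tolerance below which the base segment J2-J3 counts as degenerate
DEGENERATE_TOL = 1e-12

FEATURES_PER_JOINT = 3 + (N_JOINTS - 1) * (N_JOINTS - 2) // 2  # 81

TRUNK_JOINTS = (JointId.HEAD, JointId.NECK, JointId.RIGHT_SHOULDER,
                JointId.LEFT_SHOULDER, JointId.RIGHT_HIP, JointId.LEFT_HIP)
ARMS_JOINTS = (JointId.HEAD, JointId.NECK, JointId.RIGHT_SHOULDER,
               JointId.LEFT_SHOULDER, JointId.RIGHT_ELBOW,
               JointId.LEFT_ELBOW, JointId.RIGHT_WRIST, JointId.LEFT_WRIST)
LEGS_JOINTS = (JointId.HEAD, JointId.NECK, JointId.RIGHT_HIP,
               JointId.LEFT_HIP, JointId.RIGHT_KNEE, JointId.LEFT_KNEE,
               JointId.RIGHT_ANKLE, JointId.LEFT_ANKLE)

STREAM_DIMS = {
    "trunk": len(TRUNK_JOINTS) * FEATURES_PER_JOINT,   # 486
    "arms": len(ARMS_JOINTS) * FEATURES_PER_JOINT,     # 648
    "legs": len(LEGS_JOINTS) * FEATURES_PER_JOINT,     # 648
}


@dataclass(frozen=True)
class JointFeature:
    """81-dim descriptor of one joint: 3 coords + 78 line distances.

    ``line_distances`` follows the documented lexicographic pair order over
    the canonical JointId order, restricted to pairs not containing the
    joint itself (see :func:`pair_order`).
    """

    joint: JointId
    coords: np.ndarray
    line_distances: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.coords, self.line_distances])


@dataclass(frozen=True)
class StreamFeatures:
    """Per-stream concatenated joint features (trunk 486, arms/legs 648)."""

    trunk: np.ndarray
    arms: np.ndarray
    legs: np.ndarray

    def __post_init__(self):
        for name in ("trunk", "arms", "legs"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (STREAM_DIMS[name],):
                raise SchemaError(
                    f"{name} stream must have {STREAM_DIMS[name]} entries, "
                    f"got {v.shape}")
            object.__setattr__(self, name, v)


def joint_line_distance(j1, j2, j3) -> float:
    """Perpendicular distance from ``j1`` to the infinite line through
    ``j2`` and ``j3``, via Heron's formula: 2*sqrt(s(s-a)(s-b)(s-c))/c.

    Tiny negative radicands from rounding clamp to 0. If the base pair is
    (numerically) coincident the line is undefined; the point distance
    |j1 - j2| is returned instead so features stay finite on noisy poses.
    """
    j1, j2, j3 = (np.asarray(p, dtype=np.float64) for p in (j1, j2, j3))
    d12 = float(np.linalg.norm(j1 - j2))
    d13 = float(np.linalg.norm(j1 - j3))
    d23 = float(np.linalg.norm(j2 - j3))
    if d23 < DEGENERATE_TOL:
        return d12
    s = 0.5 * (d12 + d13 + d23)
    radicand = s * (s - d12) * (s - d13) * (s - d23)
    return 2.0 * np.sqrt(max(radicand, 0.0)) / d23


def pair_order(joint: JointId) -> list[tuple[JointId, JointId]]:
    """The 78 unordered pairs (a, b), a before b in canonical order, drawn
    from the 13 joints other than ``joint``."""
    rest = [j for j in JOINT_ORDER if j is not joint]
    return [(rest[i], rest[k])
            for i in range(len(rest)) for k in range(i + 1, len(rest))]


def _pair_index_arrays() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index triples (j, a, b) for all 14 x 78 line distances."""
    js, as_, bs = [], [], []
    for ji, joint in enumerate(JOINT_ORDER):
        for a, b in pair_order(joint):
            js.append(ji)
            as_.append(JOINT_ORDER.index(a))
            bs.append(JOINT_ORDER.index(b))
    return (np.array(js), np.array(as_), np.array(bs))

_J_IDX, _A_IDX, _B_IDX = _pair_index_arrays()


def _batch_line_distances(positions: np.ndarray) -> np.ndarray:
    """All 14 x 78 joint-line distances for a batch of frames.

    positions: (..., 14, 3) -> (..., 14, 78), Heron-based with degenerate
    fallback, fully vectorized.
    """
    diff = positions[..., :, None, :] - positions[..., None, :, :]
    dist = np.linalg.norm(diff, axis=-1)                # (..., 14, 14)
    d12 = dist[..., _J_IDX, _A_IDX]
    d13 = dist[..., _J_IDX, _B_IDX]
    d23 = dist[..., _A_IDX, _B_IDX]
    s = 0.5 * (d12 + d13 + d23)
    radicand = np.maximum(s * (s - d12) * (s - d13) * (s - d23), 0.0)
    degenerate = d23 < DEGENERATE_TOL
    out = np.where(degenerate, d12,
                   2.0 * np.sqrt(radicand) / np.where(degenerate, 1.0, d23))
    return out.reshape(positions.shape[:-2] + (N_JOINTS, 78))


def frame_features(frame: SkeletonFrame) -> dict[JointId, JointFeature]:
    """Per-joint 81-dim features for one (neck-centered) frame."""
    lines = _batch_line_distances(frame.positions)
    return {
        joint: JointFeature(joint, frame.positions[i].copy(), lines[i])
        for i, joint in enumerate(JOINT_ORDER)
    }


def split_streams(features: dict[JointId, JointFeature]) -> StreamFeatures:
    """Route per-joint features into the trunk/arms/legs streams,
    concatenating in canonical joint order within each stream."""
    missing = [j.value for j in JOINT_ORDER if j not in features]
    if missing:
        raise SchemaError(f"missing joint features: {missing}")

    def cat(joints):
        return np.concatenate([features[j].vector for j in joints])

    return StreamFeatures(trunk=cat(TRUNK_JOINTS), arms=cat(ARMS_JOINTS),
                          legs=cat(LEGS_JOINTS))


def sequence_stream_features(seq: SkeletonSequence, center: bool = True
                             ) -> dict[str, np.ndarray]:
    """Vectorized feature pipeline for a whole sequence.

    Returns arrays ``{"trunk": (n, 486), "arms": (n, 648), "legs": (n, 648)}``
    equal frame-by-frame to ``split_streams(frame_features(...))``.
    """
    positions = seq.positions_array()
    if center:
        positions = positions - positions[:, [JOINT_ORDER.index(JointId.NECK)]]
    lines = _batch_line_distances(positions)            # (n, 14, 78)
    per_joint = np.concatenate([positions, lines], axis=-1)  # (n, 14, 81)
    out = {}
    for name, joints in (("trunk", TRUNK_JOINTS), ("arms", ARMS_JOINTS),
                         ("legs", LEGS_JOINTS)):
        idx = [JOINT_ORDER.index(j) for j in joints]
        out[name] = per_joint[:, idx].reshape(len(seq), -1)
    return out


def stream_features_for_frame(frame: SkeletonFrame) -> StreamFeatures:
    """Convenience: center, featurize and split one frame."""
    return split_streams(frame_features(center_to_neck(frame)))
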