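"""Deterministic REBA (Rapid Entire Body Assessment) scoring engine.

This module turns a skeleton frame into the six-component REBA score vector
(neck, trunk, legs, upper arms, lower arms, total): joint angles are derived
from documented segment vectors, banded into the standard REBA partial
scores, combined through the published A/B/C lookup tables with
load/coupling/activity adjustments, and optionally smoothed over time with
a Savitzky-Golay filter. It serves both as the ground-truth label generator
for training the variational network and as the oracle the network is
evaluated against.

Scoring tables
--------------
The REBA framework's band thresholds and Tables A, B and C are encoded
below as fixed constants of the method (standard published values; REBA
totals are integers in [1, 15]).

Conventions
-----------
Gravity points along -y by default (configurable); the subject's facing
direction is derived from the hip line, so all sagittal/lateral splits are
body-relative. Flexion is positive forward, extension negative. The
skeleton has no hand joints, so the wrist partial entering Table B is fixed
at neutral (1). Left and right arms are scored separately and the per-frame
worst case (maximum) is used for the arm partials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import savgol_filter

from .skeleton import JointId, SkeletonFrame, SkeletonSequence

__all__ = [
    "JointAngles",
    "RebaPartialScores",
    "RebaAdjustments",
    "RebaScoreVector",
    "RiskLevel",
    "AngleUndefinedError",
    "compute_joint_angles",
    "partial_scores",
    "total_score",
    "risk_level",
    "score_frame",
    "score_sequence",
    "smooth_scores",
    "risk_distribution",
    "SCORE_COMPONENTS",
    "TABLE_A",
    "TABLE_B",
    "TABLE_C",
]

SCORE_COMPONENTS = ("neck", "trunk", "legs", "upper_arms", "lower_arms",
                    "total")

#: default gravity direction (right-handed coordinates, y up)
DEFAULT_GRAVITY = np.array([0.0, -1.0, 0.0])

_MIN_SEGMENT = 1e-9


class AngleUndefinedError(ValueError):
    """A body segment has (numerically) zero length."""


class RiskLevel(Enum):
    NEGLIGIBLE = "Negligible"
    LOW = "Low"
    MEDIUM = "Medium"
    HIGH = "High"
    VERY_HIGH = "VeryHigh"


@dataclass(frozen=True)
class JointAngles:
    """Body angles (degrees) feeding the REBA bands.

    Flexion angles are signed: positive forward (flexion), negative
    backward (extension). Booleans flag the binary REBA modifiers.
    """

    trunk_flexion: float
    trunk_side_bend: float
    trunk_twist: float
    neck_flexion: float
    neck_side_bend_or_twist: bool
    legs_knee_flexion_left: float
    legs_knee_flexion_right: float
    legs_bilateral_support: bool
    upper_arm_flexion_left: float
    upper_arm_flexion_right: float
    upper_arm_abducted_left: bool
    upper_arm_abducted_right: bool
    shoulder_raised_left: bool
    shoulder_raised_right: bool
    lower_arm_flexion_left: float
    lower_arm_flexion_right: float

    @property
    def legs_knee_flexion_max(self) -> float:
        return max(self.legs_knee_flexion_left, self.legs_knee_flexion_right)


@dataclass(frozen=True)
class RebaPartialScores:
    neck: int
    trunk: int
    legs: int
    upper_arms: int
    lower_arms: int

    _RANGES = {"neck": (1, 3), "trunk": (1, 5), "legs": (1, 4),
               "upper_arms": (1, 6), "lower_arms": (1, 2)}

    def __post_init__(self):
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ValueError(f"{name} score {v!r} outside [{lo}, {hi}]")


class Coupling(Enum):
    GOOD = 0
    FAIR = 1
    POOR = 2
    UNACCEPTABLE = 3


@dataclass(frozen=True)
class RebaAdjustments:
    """Load, coupling and activity modifiers (REBA defaults: none)."""

    load_kg: float = 0.0
    coupling: Coupling = Coupling.GOOD
    activity_static: bool = False
    activity_repeated: bool = False
    activity_rapid_change: bool = False

    def __post_init__(self):
        if self.load_kg < 0:
            raise ValueError("load_kg must be nonnegative")

    @property
    def load_score(self) -> int:
        if self.load_kg < 5:
            return 0
        if self.load_kg <= 10:
            return 1
        return 2

    @property
    def activity_score(self) -> int:
        return (int(self.activity_static) + int(self.activity_repeated)
                + int(self.activity_rapid_change))


@dataclass(frozen=True)
class RebaScoreVector:
    """The 6-component score S = (neck, trunk, legs, upper arms, lower arms,
    total). Integers before temporal smoothing, reals after."""

    neck: float
    trunk: float
    legs: float
    upper_arms: float
    lower_arms: float
    total: float

    def as_array(self) -> np.ndarray:
        return np.array([self.neck, self.trunk, self.legs, self.upper_arms,
                         self.lower_arms, self.total], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "RebaScoreVector":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (6,):
            raise ValueError(f"expected 6 components, got shape {arr.shape}")
        return cls(*arr.tolist())


# ---------------------------------------------------------------------------
# REBA lookup tables (standard published values, 1-indexed by partial score)

# TABLE_A[neck-1][trunk-1][legs-1]
TABLE_A = np.array([
    [[1, 2, 3, 4], [2, 3, 4, 5], [2, 4, 5, 6], [3, 5, 6, 7], [4, 6, 7, 8]],
    [[1, 2, 3, 4], [3, 4, 5, 6], [4, 5, 6, 7], [5, 6, 7, 8], [6, 7, 8, 9]],
    [[3, 3, 5, 6], [4, 5, 6, 7], [5, 6, 7, 8], [6, 7, 8, 9], [7, 8, 9, 9]],
], dtype=np.int64)

# TABLE_B[upper_arm-1][lower_arm-1][wrist-1]; wrist has no skeleton joint
# support here and is held at neutral (index 0) in lookups.
TABLE_B = np.array([
    [[1, 2, 2], [1, 2, 3]],
    [[1, 2, 3], [2, 3, 4]],
    [[3, 4, 5], [4, 5, 5]],
    [[4, 5, 5], [5, 6, 7]],
    [[6, 7, 8], [7, 8, 8]],
    [[7, 8, 8], [8, 9, 9]],
], dtype=np.int64)

# TABLE_C[score_a-1][score_b-1]
TABLE_C = np.array([
    [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7],
    [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8],
    [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8],
    [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9],
    [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9],
    [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10],
    [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11],
    [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11],
    [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12],
    [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12],
    [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12],
    [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12],
], dtype=np.int64)

WRIST_NEUTRAL = 1  # fixed wrist partial (no hand joints in the skeleton)

# band/modifier thresholds (degrees)
TRUNK_NEUTRAL_DEG = 5.0
TRUNK_BEND_TWIST_DEG = 10.0
NECK_FLEXION_DEG = 20.0
KNEE_BAND1_DEG = 30.0
KNEE_BAND2_DEG = 60.0
UPPER_ARM_NEUTRAL_DEG = 20.0
UPPER_ARM_MID_DEG = 45.0
UPPER_ARM_HIGH_DEG = 90.0
LOWER_ARM_LO_DEG = 60.0
LOWER_ARM_HI_DEG = 100.0
ABDUCTION_DEG = 45.0
ANKLE_SUPPORT_FRAC = 0.25   # of trunk length, for unilateral-support check
SHOULDER_RAISE_FRAC = 0.05  # of trunk length


# ---------------------------------------------------------------------------
# joint angles from geometry

def _unit(v: np.ndarray, name: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _MIN_SEGMENT:
        raise AngleUndefinedError(f"segment '{name}' has zero length")
    return v / n


def _sagittal_lateral(vec: np.ndarray, up: np.ndarray, forward: np.ndarray,
                      right: np.ndarray) -> tuple[float, float]:
    """Signed (sagittal, lateral) inclination of ``vec`` from ``up``,
    in degrees. Sagittal positive toward ``forward``, lateral toward
    ``right``."""
    u = np.dot(vec, up)
    f = np.dot(vec, forward)
    r = np.dot(vec, right)
    sag = np.degrees(np.arctan2(f, u))
    lat = np.degrees(np.arctan2(r, np.hypot(f, u)))
    return float(sag), float(lat)


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    cosang = np.clip(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)),
                     -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_joint_angles(frame: SkeletonFrame,
                         gravity_axis: np.ndarray = DEFAULT_GRAVITY
                         ) -> JointAngles:
    """Derive the REBA-relevant body angles from raw joint coordinates.

    Segment conventions:

    * trunk      — mid-hip -> neck, measured against -gravity; the sagittal
      component is trunk flexion, the lateral one side bending; trunk twist
      is the horizontal angle between the shoulder and hip lines
    * neck       — neck -> head relative to the trunk direction
    * knees      — interior angle hip-knee-ankle, 0 = straight leg
    * upper arm  — shoulder -> elbow against the downward trunk direction
    * lower arm  — 180 deg minus the interior elbow angle, 0 = straight arm
    """
    g = _unit(np.asarray(gravity_axis, dtype=np.float64), "gravity")
    up = -g
    p = frame.as_mapping()

    mid_hip = 0.5 * (p[JointId.RIGHT_HIP] + p[JointId.LEFT_HIP])
    trunk_vec = p[JointId.NECK] - mid_hip
    trunk_dir = _unit(trunk_vec, "trunk (mid-hip to neck)")
    trunk_len = np.linalg.norm(trunk_vec)

    hip_axis = p[JointId.RIGHT_HIP] - p[JointId.LEFT_HIP]
    # body-frame axes: right along the hip line (projected horizontal),
    # forward = up x right (right-handed, subject faces `forward`)
    right = hip_axis - np.dot(hip_axis, up) * up
    right = _unit(right, "hip line (right axis)")
    forward = np.cross(up, right)

    trunk_flexion, trunk_side = _sagittal_lateral(trunk_dir, up, forward,
                                                  right)

    shoulder_axis = p[JointId.RIGHT_SHOULDER] - p[JointId.LEFT_SHOULDER]
    sh_h = shoulder_axis - np.dot(shoulder_axis, trunk_dir) * trunk_dir
    hip_h = hip_axis - np.dot(hip_axis, trunk_dir) * trunk_dir
    if (np.linalg.norm(sh_h) < _MIN_SEGMENT
            or np.linalg.norm(hip_h) < _MIN_SEGMENT):
        trunk_twist = 0.0
    else:
        trunk_twist = _angle_between(sh_h, hip_h)

    # neck relative to trunk: flexion in the sagittal plane, lateral part
    # flags the side-bend/twist modifier
    neck_vec = _unit(p[JointId.HEAD] - p[JointId.NECK], "neck (neck to head)")
    neck_sag = np.degrees(np.arctan2(np.dot(neck_vec, forward),
                                     np.dot(neck_vec, trunk_dir)))
    neck_lat = np.degrees(np.arcsin(np.clip(np.dot(neck_vec, right),
                                            -1.0, 1.0)))
    neck_side = abs(neck_lat) > TRUNK_BEND_TWIST_DEG

    def knee_flexion(side: str) -> float:
        hip = p[JointId[f"{side}_HIP"]]
        knee = p[JointId[f"{side}_KNEE"]]
        ankle = p[JointId[f"{side}_ANKLE"]]
        thigh = _unit(knee - hip, f"{side.lower()} thigh")
        shank = _unit(ankle - knee, f"{side.lower()} shank")
        return _angle_between(thigh, shank)

    knee_l = knee_flexion("LEFT")
    knee_r = knee_flexion("RIGHT")

    ankle_gap = abs(np.dot(p[JointId.RIGHT_ANKLE] - p[JointId.LEFT_ANKLE],
                           up))
    bilateral = ankle_gap < ANKLE_SUPPORT_FRAC * trunk_len

    down_trunk = -trunk_dir

    def arm(side: str):
        shoulder = p[JointId[f"{side}_SHOULDER"]]
        elbow = p[JointId[f"{side}_ELBOW"]]
        wrist = p[JointId[f"{side}_WRIST"]]
        ua = _unit(elbow - shoulder, f"{side.lower()} upper arm")
        # flexion = arm elevation away from the hanging-down trunk
        # direction, signed by its sagittal component (forward positive);
        # a purely lateral raise keeps the positive sign and additionally
        # trips the abduction modifier
        elevation = _angle_between(ua, down_trunk)
        sag = np.dot(ua, forward)
        flexion = -elevation if sag < -1e-9 else elevation
        lat_sign = 1.0 if side == "RIGHT" else -1.0
        ua_lat = np.degrees(np.arcsin(np.clip(
            lat_sign * np.dot(ua, right), -1.0, 1.0)))
        abducted = ua_lat > ABDUCTION_DEG
        _unit(wrist - elbow, f"{side.lower()} forearm")  # validate segment
        lower_flex = 180.0 - _angle_between(shoulder - elbow, wrist - elbow)
        raised = (np.dot(shoulder - p[JointId.NECK], up)
                  > SHOULDER_RAISE_FRAC * trunk_len)
        return float(flexion), bool(abducted), bool(raised), float(lower_flex)

    ua_l, abd_l, raise_l, la_l = arm("LEFT")
    ua_r, abd_r, raise_r, la_r = arm("RIGHT")

    return JointAngles(
        trunk_flexion=trunk_flexion,
        trunk_side_bend=trunk_side,
        trunk_twist=trunk_twist,
        neck_flexion=float(neck_sag),
        neck_side_bend_or_twist=bool(neck_side),
        legs_knee_flexion_left=knee_l,
        legs_knee_flexion_right=knee_r,
        legs_bilateral_support=bool(bilateral),
        upper_arm_flexion_left=ua_l,
        upper_arm_flexion_right=ua_r,
        upper_arm_abducted_left=abd_l,
        upper_arm_abducted_right=abd_r,
        shoulder_raised_left=raise_l,
        shoulder_raised_right=raise_r,
        lower_arm_flexion_left=la_l,
        lower_arm_flexion_right=la_r,
    )


# ---------------------------------------------------------------------------
# band scoring

def _trunk_score(a: JointAngles) -> int:
    f = a.trunk_flexion
    if abs(f) <= TRUNK_NEUTRAL_DEG:
        s = 1
    elif -20.0 <= f <= 20.0:
        s = 2
    elif 20.0 < f <= 60.0 or f < -20.0:
        s = 3
    else:  # f > 60
        s = 4
    if (abs(a.trunk_side_bend) > TRUNK_BEND_TWIST_DEG
            or a.trunk_twist > TRUNK_BEND_TWIST_DEG):
        s += 1
    return min(s, 5)


def _neck_score(a: JointAngles) -> int:
    s = 1 if 0.0 <= a.neck_flexion <= NECK_FLEXION_DEG else 2
    if a.neck_side_bend_or_twist:
        s += 1
    return min(s, 3)


def _legs_score(a: JointAngles) -> int:
    s = 1 if a.legs_bilateral_support else 2
    k = a.legs_knee_flexion_max
    if k > KNEE_BAND2_DEG:
        s += 2
    elif k > KNEE_BAND1_DEG:
        s += 1
    return min(s, 4)


def _upper_arm_score(flexion: float, abducted: bool, raised: bool) -> int:
    f = flexion
    if -UPPER_ARM_NEUTRAL_DEG <= f <= UPPER_ARM_NEUTRAL_DEG:
        s = 1
    elif f <= UPPER_ARM_MID_DEG:  # 20-45 flexion or >20 extension
        s = 2
    elif f <= UPPER_ARM_HIGH_DEG:
        s = 3
    else:
        s = 4
    if abducted:
        s += 1
    if raised:
        s += 1
    return min(s, 6)


def _lower_arm_score(flexion: float) -> int:
    return 1 if LOWER_ARM_LO_DEG <= flexion <= LOWER_ARM_HI_DEG else 2


def partial_scores(angles: JointAngles) -> RebaPartialScores:
    """Apply the REBA band thresholds to the measured angles.

    Arms are scored per side and the worst (maximum) side is kept.
    """
    ua = max(
        _upper_arm_score(angles.upper_arm_flexion_left,
                         angles.upper_arm_abducted_left,
                         angles.shoulder_raised_left),
        _upper_arm_score(angles.upper_arm_flexion_right,
                         angles.upper_arm_abducted_right,
                         angles.shoulder_raised_right),
    )
    la = max(_lower_arm_score(angles.lower_arm_flexion_left),
             _lower_arm_score(angles.lower_arm_flexion_right))
    return RebaPartialScores(
        neck=_neck_score(angles),
        trunk=_trunk_score(angles),
        legs=_legs_score(angles),
        upper_arms=ua,
        lower_arms=la,
    )


def total_score(partials: RebaPartialScores,
                adj: RebaAdjustments = RebaAdjustments()) -> int:
    """Combine partials through Tables A, B and C with the adjustments.

    score A = Table A(neck, trunk, legs) + load; score B = Table B(upper
    arm, lower arm, neutral wrist) + coupling; total = Table C(A, B) +
    activity, clamped to [1, 15].
    """
    a = TABLE_A[partials.neck - 1, partials.trunk - 1, partials.legs - 1]
    a = int(a) + adj.load_score
    b = TABLE_B[partials.upper_arms - 1, partials.lower_arms - 1,
                WRIST_NEUTRAL - 1]
    b = int(b) + adj.coupling.value
    c = TABLE_C[min(a, 12) - 1, min(b, 12) - 1]
    return int(np.clip(int(c) + adj.activity_score, 1, 15))


_RISK_BINS = ((2.0, RiskLevel.NEGLIGIBLE), (4.0, RiskLevel.LOW),
              (8.0, RiskLevel.MEDIUM), (11.0, RiskLevel.HIGH),
              (np.inf, RiskLevel.VERY_HIGH))


def risk_level(total: float) -> RiskLevel:
    """Bin a total score into the REBA risk level:
    Negligible (<2), Low [2,4), Medium [4,8), High [8,11), Very High (>=11).
    """
    if not np.isfinite(total):
        raise ValueError("total score must be finite")
    for upper, level in _RISK_BINS:
        if total < upper:
            return level
    return RiskLevel.VERY_HIGH


def score_frame(frame: SkeletonFrame,
                adj: RebaAdjustments = RebaAdjustments(),
                gravity_axis: np.ndarray = DEFAULT_GRAVITY
                ) -> RebaScoreVector:
    angles = compute_joint_angles(frame, gravity_axis)
    p = partial_scores(angles)
    return RebaScoreVector(p.neck, p.trunk, p.legs, p.upper_arms,
                           p.lower_arms, total_score(p, adj))


def score_sequence(seq: SkeletonSequence,
                   adj: RebaAdjustments = RebaAdjustments(),
                   gravity_axis: np.ndarray = DEFAULT_GRAVITY
                   ) -> list[RebaScoreVector]:
    """Per-frame unsmoothed integer score vectors."""
    out = []
    for f in seq.frames:
        try:
            out.append(score_frame(f, adj, gravity_axis))
        except AngleUndefinedError as e:
            raise AngleUndefinedError(
                f"frame {f.frame_index}: {e}") from e
    return out


def smooth_scores(scores: list[RebaScoreVector], window: int = 13,
                  polyorder: int = 3) -> list[RebaScoreVector]:
    """Savitzky-Golay smoothing of each score component independently.

    Piece-wise-constant integer score traces are hard regression targets;
    low-order polynomial smoothing turns them into gentle real-valued
    curves. Even windows are normalized up to the next odd integer (the
    filter requires odd windows). Sequences shorter than the window are
    returned unchanged with a warning. Edges use scipy's polynomial
    interpolation mode so output length equals input length.
    """
    if window < 1 or polyorder < 1:
        raise ValueError("window and polyorder must be positive")
    if window % 2 == 0:
        window += 1
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    if len(scores) < window:
        warnings.warn(
            f"sequence of {len(scores)} frames is shorter than the "
            f"smoothing window {window}; returning scores unsmoothed",
            stacklevel=2)
        return list(scores)
    arr = np.stack([s.as_array() for s in scores])
    smoothed = savgol_filter(arr, window, polyorder, axis=0, mode="interp")
    return [RebaScoreVector.from_array(row) for row in smoothed]


def risk_distribution(scores: list[RebaScoreVector]
                      ) -> dict[RiskLevel, float]:
    """Percentage of frames per risk level (sums to 100)."""
    if not scores:
        raise ValueError("risk_distribution needs at least one score")
    counts = {level: 0 for level in RiskLevel}
    for s in scores:
        counts[risk_level(s.total)] += 1
    n = len(scores)
    return {level: 100.0 * c / n for level, c in counts.items()}
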