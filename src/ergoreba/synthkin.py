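"""Synthetic articulated human motion with known REBA labels.

Sequences are generated by sampling one smooth, bounded trajectory per
degree of freedom (an Ornstein-Uhlenbeck mean-reverting walk squashed
through tanh into an anatomical range, then low-pass filtered) and running
forward kinematics over a canonical 13-bone tree rooted at the pelvis.
Bone lengths are 50th-percentile adult segment lengths (meters) and are
exact in every frame by construction; REBA depends only on angles, so the
anthropometry does not bias the labels.

Three posture regimes set the trajectory centers/amplitudes:

* ``neutral`` — upright standing, elbows at ~80 deg, everything inside the
  lowest REBA bands (per-frame total = 1)
* ``mixed``   — everyday manual work: trunk flexion up to ~60 deg, reaching
  and asymmetric stances, spanning Low through High risk
* ``extreme`` — deep trunk flexion with raised/abducted arms and a bent
  single-leg stance, reaching Very High (total >= 11) postures

The labeling pipeline (simulate -> neck-center -> features -> rule-engine
scores -> Savitzky-Golay smoothing) mirrors exactly how ground-truth labels
are produced for real recordings, minus the RGB->pose step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .features import sequence_stream_features
from .reba import RebaAdjustments, score_sequence, smooth_scores
from .skeleton import JointId, SkeletonSequence
from .training import LabeledDataset

__all__ = ["KinematicConfig", "simulate_sequence", "make_labeled_dataset",
           "DEFAULT_BONES", "BONE_JOINT_PAIRS"]

#: segment lengths in meters (50th-percentile adult)
DEFAULT_BONES = {
    "trunk": 0.50,        # mid-hip -> neck
    "pelvis": 0.20,       # hip -> hip
    "head": 0.25,         # neck -> head
    "clavicle_left": 0.19,
    "clavicle_right": 0.19,
    "upper_arm_left": 0.30,
    "upper_arm_right": 0.30,
    "forearm_left": 0.27,
    "forearm_right": 0.27,
    "thigh_left": 0.42,
    "thigh_right": 0.42,
    "shank_left": 0.42,
    "shank_right": 0.42,
}

#: joint pairs whose distance equals a configured bone length in every frame
BONE_JOINT_PAIRS = {
    "pelvis": (JointId.RIGHT_HIP, JointId.LEFT_HIP),
    "head": (JointId.NECK, JointId.HEAD),
    "clavicle_left": (JointId.NECK, JointId.LEFT_SHOULDER),
    "clavicle_right": (JointId.NECK, JointId.RIGHT_SHOULDER),
    "upper_arm_left": (JointId.LEFT_SHOULDER, JointId.LEFT_ELBOW),
    "upper_arm_right": (JointId.RIGHT_SHOULDER, JointId.RIGHT_ELBOW),
    "forearm_left": (JointId.LEFT_ELBOW, JointId.LEFT_WRIST),
    "forearm_right": (JointId.RIGHT_ELBOW, JointId.RIGHT_WRIST),
    "thigh_left": (JointId.LEFT_HIP, JointId.LEFT_KNEE),
    "thigh_right": (JointId.RIGHT_HIP, JointId.RIGHT_KNEE),
    "shank_left": (JointId.LEFT_KNEE, JointId.LEFT_ANKLE),
    "shank_right": (JointId.RIGHT_KNEE, JointId.RIGHT_ANKLE),
}

# per-regime (center, amplitude) in degrees for every degree of freedom;
# the realized angle is center + amplitude * tanh(OU walk)
_REGIMES = {
    "neutral": {
        "trunk_flexion": (0, 2), "trunk_side": (0, 2), "trunk_twist": (0, 3),
        "neck_flexion": (8, 5), "neck_side": (0, 3),
        "hip_flexion_left": (0, 3), "hip_flexion_right": (0, 3),
        "knee_left": (5, 5), "knee_right": (5, 5),
        "ua_flexion_left": (0, 8), "ua_flexion_right": (0, 8),
        "ua_abduction_left": (0, 5), "ua_abduction_right": (0, 5),
        "elbow_left": (80, 10), "elbow_right": (80, 10),
        "shoulder_elev": (0, 2),
    },
    "mixed": {
        "trunk_flexion": (25, 35), "trunk_side": (0, 12),
        "trunk_twist": (0, 15),
        "neck_flexion": (10, 18), "neck_side": (0, 12),
        "hip_flexion_left": (15, 20), "hip_flexion_right": (10, 15),
        "knee_left": (20, 30), "knee_right": (15, 25),
        "ua_flexion_left": (30, 55), "ua_flexion_right": (35, 55),
        "ua_abduction_left": (10, 25), "ua_abduction_right": (10, 25),
        "elbow_left": (50, 45), "elbow_right": (55, 45),
        "shoulder_elev": (5, 8),
    },
    "extreme": {
        "trunk_flexion": (70, 25), "trunk_side": (15, 15),
        "trunk_twist": (20, 15),
        "neck_flexion": (28, 20), "neck_side": (14, 10),
        "hip_flexion_left": (40, 30), "hip_flexion_right": (15, 15),
        "knee_left": (70, 25), "knee_right": (15, 15),
        "ua_flexion_left": (110, 40), "ua_flexion_right": (110, 40),
        "ua_abduction_left": (40, 25), "ua_abduction_right": (40, 25),
        "elbow_left": (120, 40), "elbow_right": (120, 40),
        "shoulder_elev": (12, 6),
    },
}

_ANGLE_LIMITS = {  # hard anatomical clamps (degrees)
    "trunk_flexion": (-30, 110), "trunk_side": (-40, 40),
    "trunk_twist": (-45, 45), "neck_flexion": (-40, 60),
    "neck_side": (-35, 35),
    "hip_flexion_left": (-15, 110), "hip_flexion_right": (-15, 110),
    "knee_left": (0, 135), "knee_right": (0, 135),
    "ua_flexion_left": (-40, 170), "ua_flexion_right": (-40, 170),
    "ua_abduction_left": (-10, 90), "ua_abduction_right": (-10, 90),
    "elbow_left": (0, 150), "elbow_right": (0, 150),
    "shoulder_elev": (-5, 25),
}


@dataclass
class KinematicConfig:
    bone_lengths: dict = field(default_factory=lambda: dict(DEFAULT_BONES))
    fps: float = 30.0
    duration: float = 20.0
    regime: str = "mixed"
    smoothness: float = 0.05  # low-pass cutoff as a fraction of fps
    seed: int = 0
    angle_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.regime not in _REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; "
                f"choose from {sorted(_REGIMES)}")
        if any(v <= 0 for v in self.bone_lengths.values()):
            raise ValueError("bone lengths must be positive")
        if not 0 < self.smoothness < 0.5:
            raise ValueError("smoothness must lie in (0, 0.5)")
        for name, (center, amp) in {**_REGIMES[self.regime],
                                    **self.angle_overrides}.items():
            if name not in _ANGLE_LIMITS:
                raise ValueError(f"unknown degree of freedom {name!r}")
            lo, hi = _ANGLE_LIMITS[name]
            if amp < 0 or center + amp < lo or center - amp > hi:
                # trajectories are clipped at the anatomical limits; only a
                # range lying entirely outside them is impossible
                raise ValueError(
                    f"angle range for '{name}' ({center}+-{amp}) lies "
                    f"outside anatomical limits [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return max(2, int(round(self.fps * self.duration)))


def _ou_angles(cfg: KinematicConfig, rng: np.random.Generator
               ) -> dict[str, np.ndarray]:
    """One smooth bounded trajectory per degree of freedom."""
    n = cfg.n_frames
    dt = 1.0 / cfg.fps
    theta, sigma = 0.8, 1.1  # mean-reversion rate (1/s), diffusion
    spec = {**_REGIMES[cfg.regime], **cfg.angle_overrides}
    window = int(round(1.0 / cfg.smoothness))
    window += 1 - window % 2  # odd
    out = {}
    for name in sorted(spec):
        center, amp = spec[name]
        x = np.empty(n)
        x[0] = rng.standard_normal()
        noise = rng.standard_normal(n - 1)
        for t in range(n - 1):
            x[t + 1] = x[t] - theta * x[t] * dt + sigma * np.sqrt(dt) * noise[t]
        ang = center + amp * np.tanh(x)
        if n > window >= 5:
            ang = savgol_filter(ang, window, 3, mode="interp")
        lo, hi = _ANGLE_LIMITS[name]
        out[name] = np.clip(ang, lo, hi)
    return out


def _rodrigues(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    th = np.radians(deg)
    return (v * np.cos(th) + np.cross(a, v) * np.sin(th)
            + a * np.dot(a, v) * (1.0 - np.cos(th)))


def simulate_sequence(cfg: KinematicConfig) -> SkeletonSequence:
    """Forward kinematics over the canonical tree; exact bone lengths."""
    rng = np.random.default_rng(cfg.seed)
    ang = _ou_angles(cfg, rng)
    b = cfg.bone_lengths
    up = np.array([0.0, 1.0, 0.0])
    fwd0 = np.array([1.0, 0.0, 0.0])
    right0 = np.array([0.0, 0.0, 1.0])
    n = cfg.n_frames
    # slow pelvis drift: absolute position should not matter downstream
    drift = np.cumsum(rng.normal(0, 0.002, size=(n, 3)), axis=0)

    frames = np.empty((n, 14, 3))
    J = {j: i for i, j in enumerate(JointId)}
    for t in range(n):
        pelvis = drift[t] + np.array([0.0, b["thigh_left"] + b["shank_left"],
                                      0.0])
        tf, ts = ang["trunk_flexion"][t], ang["trunk_side"][t]
        # rotating about +right0 moves `up` backward; negate for forward
        trunk_dir = _rodrigues(up, right0, -tf)
        trunk_dir = _rodrigues(trunk_dir, fwd0, ts)
        neck = pelvis + trunk_dir * b["trunk"]
        hip_r = pelvis + right0 * (b["pelvis"] / 2)
        hip_l = pelvis - right0 * (b["pelvis"] / 2)

        # trunk-local frame, twisted shoulder line
        t_up = trunk_dir
        t_right = _rodrigues(right0, up, 0.0)
        t_right = t_right - np.dot(t_right, t_up) * t_up
        t_right /= np.linalg.norm(t_right)
        t_right = _rodrigues(t_right, t_up, ang["trunk_twist"][t])
        t_fwd = np.cross(t_up, t_right)

        e = ang["shoulder_elev"][t]
        clav_r = (np.cos(np.radians(e)) * t_right
                  + np.sin(np.radians(e)) * t_up)
        clav_l = (-np.cos(np.radians(e)) * t_right
                  + np.sin(np.radians(e)) * t_up)
        sho_r = neck + clav_r * b["clavicle_right"]
        sho_l = neck + clav_l * b["clavicle_left"]

        head_dir = _rodrigues(t_up, t_right, -ang["neck_flexion"][t])
        head_dir = _rodrigues(head_dir, t_fwd, ang["neck_side"][t])
        head = neck + head_dir * b["head"]

        def arm(side: str, sho, lat_axis):
            ua_dir = _rodrigues(-t_up, t_right, ang[f"ua_flexion_{side}"][t])
            ua_dir = _rodrigues(ua_dir, t_fwd,
                                -ang[f"ua_abduction_{side}"][t]
                                if lat_axis > 0
                                else ang[f"ua_abduction_{side}"][t])
            elbow = sho + ua_dir * b[f"upper_arm_{side}"]
            fa_dir = _rodrigues(ua_dir, t_right, ang[f"elbow_{side}"][t])
            wrist = elbow + fa_dir * b[f"forearm_{side}"]
            return elbow, wrist

        elb_r, wri_r = arm("right", sho_r, +1)
        elb_l, wri_l = arm("left", sho_l, -1)

        def leg(side: str, hip):
            thigh_dir = _rodrigues(-up, right0, ang[f"hip_flexion_{side}"][t])
            knee = hip + thigh_dir * b[f"thigh_{side}"]
            shank_dir = _rodrigues(thigh_dir, right0,
                                   -ang[f"knee_{side}"][t])
            ankle = knee + shank_dir * b[f"shank_{side}"]
            return knee, ankle

        knee_r, ank_r = leg("right", hip_r)
        knee_l, ank_l = leg("left", hip_l)

        frames[t, J[JointId.HEAD]] = head
        frames[t, J[JointId.NECK]] = neck
        frames[t, J[JointId.RIGHT_SHOULDER]] = sho_r
        frames[t, J[JointId.LEFT_SHOULDER]] = sho_l
        frames[t, J[JointId.RIGHT_ELBOW]] = elb_r
        frames[t, J[JointId.LEFT_ELBOW]] = elb_l
        frames[t, J[JointId.RIGHT_WRIST]] = wri_r
        frames[t, J[JointId.LEFT_WRIST]] = wri_l
        frames[t, J[JointId.RIGHT_HIP]] = hip_r
        frames[t, J[JointId.LEFT_HIP]] = hip_l
        frames[t, J[JointId.RIGHT_KNEE]] = knee_r
        frames[t, J[JointId.LEFT_KNEE]] = knee_l
        frames[t, J[JointId.RIGHT_ANKLE]] = ank_r
        frames[t, J[JointId.LEFT_ANKLE]] = ank_l

    return SkeletonSequence.from_array(frames, fps=cfg.fps)


def make_labeled_dataset(cfg: KinematicConfig, n_sequences: int,
                         smoothing_window: int = 13, polyorder: int = 3,
                         adjustments: RebaAdjustments = RebaAdjustments()
                         ) -> LabeledDataset:
    """Simulate, featurize and label ``n_sequences`` independent sequences.

    Labels follow the reference pipeline: rule-engine integer scores per
    frame, then per-component Savitzky-Golay smoothing. Frames are grouped
    by sequence id for leakage-free fold splitting.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    streams = {"trunk": [], "arms": [], "legs": []}
    targets, groups = [], []
    for i in range(n_sequences):
        seq = simulate_sequence(replace(cfg, seed=cfg.seed + i))
        feats = sequence_stream_features(seq, center=True)
        scores = smooth_scores(score_sequence(seq, adjustments),
                               smoothing_window, polyorder)
        for k in streams:
            streams[k].append(feats[k])
        targets.append(np.stack([s.as_array() for s in scores]))
        groups.append(np.full(len(seq), i))
    return LabeledDataset(
        {k: np.concatenate(v) for k, v in streams.items()},
        np.concatenate(targets), np.concatenate(groups))
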