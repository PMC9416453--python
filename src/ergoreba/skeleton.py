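"""14-joint skeleton data model and pose-sequence I/O.

The canonical skeleton uses 14 widely available joints (head, neck and
left/right shoulder, elbow, wrist, hip, knee, ankle) — the set emitted by
most monocular 3D pose estimators. Coordinates are right-handed with
gravity along -y by default (configurable where angles are computed);
lengths are in consistent but arbitrary units.

Supported sequence dialects:

* ``csv``   — header ``frame,<joint>_x,<joint>_y,<joint>_z,...``
* ``jsonl`` — one JSON object per frame with joint-name keys and an
  optional ``frame`` index; first line may be a ``{"fps": ...}`` header
* ``npz``   — columnar binary with arrays ``positions`` (frames x 14 x 3)
  and scalar ``fps``
"""

from __future__ import annotations

import csv as _csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JointId",
    "SkeletonFrame",
    "SkeletonSequence",
    "SchemaError",
    "ValidationError",
    "read_sequence",
    "write_sequence",
    "center_to_neck",
    "N_JOINTS",
]


class JointId(Enum):
    """Canonical joint enumeration. Member order is the canonical order used
    for every serialized vector in the package; do not reorder."""

    HEAD = "Head"
    NECK = "Neck"
    RIGHT_SHOULDER = "RightShoulder"
    LEFT_SHOULDER = "LeftShoulder"
    RIGHT_ELBOW = "RightElbow"
    LEFT_ELBOW = "LeftElbow"
    RIGHT_WRIST = "RightWrist"
    LEFT_WRIST = "LeftWrist"
    RIGHT_HIP = "RightHip"
    LEFT_HIP = "LeftHip"
    RIGHT_KNEE = "RightKnee"
    LEFT_KNEE = "LeftKnee"
    RIGHT_ANKLE = "RightAnkle"
    LEFT_ANKLE = "LeftAnkle"

    @property
    def mirror(self) -> "JointId":
        """Left/right partner; Head and Neck are their own mirror."""
        name = self.name
        if name.startswith("RIGHT_"):
            return JointId["LEFT_" + name[6:]]
        if name.startswith("LEFT_"):
            return JointId["RIGHT_" + name[5:]]
        return self


JOINT_ORDER: tuple[JointId, ...] = tuple(JointId)
N_JOINTS = len(JOINT_ORDER)
assert N_JOINTS == 14


class SchemaError(ValueError):
    """Input does not match the declared joint schema."""


class ValidationError(ValueError):
    """Input matches the schema but carries invalid values."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One time instant: a mapping JointId -> 3D position.

    Positions are stored internally as a (14, 3) float64 array in canonical
    joint order.
    """

    positions: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        arr = np.asarray(self.positions, dtype=np.float64)
        if arr.shape != (N_JOINTS, 3):
            raise SchemaError(
                f"frame {self.frame_index}: expected positions of shape "
                f"(14, 3), got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            bad = [JOINT_ORDER[i].value
                   for i in np.nonzero(~np.isfinite(arr).all(axis=1))[0]]
            raise ValidationError(
                f"frame {self.frame_index}: non-finite coordinates for {bad}"
            )
        if self.frame_index < 0:
            raise ValidationError("frame_index must be nonnegative")
        object.__setattr__(self, "positions", arr)

    @classmethod
    def from_mapping(cls, m: Mapping[JointId, Sequence[float]],
                     frame_index: int = 0) -> "SkeletonFrame":
        missing = [j.value for j in JOINT_ORDER if j not in m]
        if missing:
            raise SchemaError(f"missing joints: {missing}")
        arr = np.array([m[j] for j in JOINT_ORDER], dtype=np.float64)
        return cls(arr, frame_index)

    def __getitem__(self, joint: JointId) -> np.ndarray:
        return self.positions[JOINT_ORDER.index(joint)]

    def as_mapping(self) -> dict[JointId, np.ndarray]:
        return {j: self.positions[i] for i, j in enumerate(JOINT_ORDER)}


@dataclass
class SkeletonSequence:
    """Ordered frames plus the capture frame rate."""

    frames: list[SkeletonFrame]
    fps: float = 30.0

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("sequence must contain at least one frame")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterable[SkeletonFrame]:
        return iter(self.frames)

    def positions_array(self) -> np.ndarray:
        """(n_frames, 14, 3) stacked positions in canonical joint order."""
        return np.stack([f.positions for f in self.frames])

    @classmethod
    def from_array(cls, positions: np.ndarray, fps: float = 30.0,
                   frame_indices: Sequence[int] | None = None
                   ) -> "SkeletonSequence":
        positions = np.asarray(positions, dtype=np.float64)
        if positions.ndim != 3 or positions.shape[1:] != (N_JOINTS, 3):
            raise SchemaError(
                f"expected (n, 14, 3) positions, got {positions.shape}")
        if frame_indices is None:
            frame_indices = range(len(positions))
        frames = [SkeletonFrame(p, int(i))
                  for p, i in zip(positions, frame_indices)]
        return cls(frames, fps=fps)


def center_to_neck(frame: SkeletonFrame) -> SkeletonFrame:
    """Translate all joints so the neck sits exactly at the origin.

    Removes dependence on the subject's absolute position; inter-joint
    distances are untouched. Idempotent.
    """
    neck = frame[JointId.NECK]
    return SkeletonFrame(frame.positions - neck, frame.frame_index)


def center_sequence(seq: SkeletonSequence) -> SkeletonSequence:
    return SkeletonSequence([center_to_neck(f) for f in seq.frames],
                            fps=seq.fps)


#: joint pairs treated as bones for scale estimation
BONE_PAIRS: tuple[tuple[JointId, JointId], ...] = (
    (JointId.NECK, JointId.HEAD),
    (JointId.NECK, JointId.RIGHT_SHOULDER),
    (JointId.NECK, JointId.LEFT_SHOULDER),
    (JointId.RIGHT_SHOULDER, JointId.RIGHT_ELBOW),
    (JointId.LEFT_SHOULDER, JointId.LEFT_ELBOW),
    (JointId.RIGHT_ELBOW, JointId.RIGHT_WRIST),
    (JointId.LEFT_ELBOW, JointId.LEFT_WRIST),
    (JointId.RIGHT_HIP, JointId.LEFT_HIP),
    (JointId.RIGHT_HIP, JointId.RIGHT_KNEE),
    (JointId.LEFT_HIP, JointId.LEFT_KNEE),
    (JointId.RIGHT_KNEE, JointId.RIGHT_ANKLE),
    (JointId.LEFT_KNEE, JointId.LEFT_ANKLE),
)


def normalize_scale(seq: SkeletonSequence) -> SkeletonSequence:
    """Divide all coordinates by the sequence's mean bone length.

    Joint-line distance features are scale-covariant, so training and
    inference data must share one length scale; this opt-in normalization
    makes sequences from differently calibrated pose estimators
    comparable.
    """
    positions = seq.positions_array()
    idx = {j: i for i, j in enumerate(JOINT_ORDER)}
    lengths = [np.linalg.norm(positions[:, idx[a]] - positions[:, idx[b]],
                              axis=1) for a, b in BONE_PAIRS]
    scale = float(np.mean(lengths))
    if scale < 1e-12:
        raise ValidationError("cannot normalize: mean bone length is zero")
    return SkeletonSequence.from_array(
        positions / scale, fps=seq.fps,
        frame_indices=[f.frame_index for f in seq.frames])


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = ["frame"] + [f"{j.value}_{ax}" for j in JOINT_ORDER
                            for ax in "xyz"]

_DIALECTS = ("csv", "jsonl", "npz")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _DIALECTS:
        return suffix
    raise ValueError(
        f"cannot infer dialect from '{path.name}'; pass dialect explicitly")


def write_sequence(seq: SkeletonSequence, path, dialect: str | None = None
                   ) -> None:
    """Write a sequence in one of the supported dialects (lossless)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(_CSV_COLUMNS + ["fps"])
            for k, f in enumerate(seq.frames):
                row = [f.frame_index] + [repr(float(v))
                                         for v in f.positions.ravel()]
                row.append(repr(float(seq.fps)) if k == 0 else "")
                w.writerow(row)
    elif dialect == "jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps({"fps": seq.fps}) + "\n")
            for f in seq.frames:
                rec = {"frame": f.frame_index}
                rec.update({j.value: list(f.positions[i])
                            for i, j in enumerate(JOINT_ORDER)})
                fh.write(json.dumps(rec) + "\n")
    elif dialect == "npz":
        np.savez(
            path,
            positions=seq.positions_array(),
            frame_indices=np.array([f.frame_index for f in seq.frames]),
            fps=np.float64(seq.fps),
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sequence(path, dialect: str | None = None) -> SkeletonSequence:
    """Read and validate a pose sequence.

    Raises :class:`SchemaError` for missing joint columns and
    :class:`ValidationError` for non-finite values (naming the frame).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "jsonl":
        return _read_jsonl(path)
    if dialect == "npz":
        return _read_npz(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: Path) -> SkeletonSequence:
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise SchemaError("empty CSV file")
        has_fps = header and header[-1] == "fps"
        core = header[:-1] if has_fps else header
        missing = [c for c in _CSV_COLUMNS if c not in core]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        col_idx = [core.index(c) for c in _CSV_COLUMNS]
        fps = 30.0
        frames = []
        for n, row in enumerate(reader):
            if has_fps and n == 0 and row[-1]:
                fps = float(row[-1])
            vals = [row[i] for i in col_idx]
            idx = int(float(vals[0]))
            coords = np.array(vals[1:], dtype=np.float64).reshape(N_JOINTS, 3)
            frames.append(SkeletonFrame(coords, idx))
        if not frames:
            raise ValidationError("CSV contains a header but no frames")
    return SkeletonSequence(frames, fps=fps)


def _read_jsonl(path: Path) -> SkeletonSequence:
    fps = 30.0
    frames = []
    with open(path) as fh:
        for n, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if set(rec) == {"fps"}:
                fps = float(rec["fps"])
                continue
            missing = [j.value for j in JOINT_ORDER if j.value not in rec]
            if missing:
                raise SchemaError(
                    f"line {n + 1}: missing joints: {missing}")
            idx = int(rec.get("frame", len(frames)))
            coords = np.array([rec[j.value] for j in JOINT_ORDER],
                              dtype=np.float64)
            if coords.shape != (N_JOINTS, 3):
                raise SchemaError(
                    f"line {n + 1}: each joint needs exactly 3 coordinates")
            frames.append(SkeletonFrame(coords, idx))
    if not frames:
        raise ValidationError("JSONL file contains no frames")
    return SkeletonSequence(frames, fps=fps)


def _read_npz(path: Path) -> SkeletonSequence:
    with np.load(path) as data:
        if "positions" not in data:
            raise SchemaError("npz archive lacks a 'positions' array")
        positions = data["positions"]
        fps = float(data["fps"]) if "fps" in data else 30.0
        indices = (data["frame_indices"] if "frame_indices" in data
                   else np.arange(len(positions)))
    return SkeletonSequence.from_array(positions, fps=fps,
                                       frame_indices=indices)
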