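"""Data model and CSV serialization for skeletal motion trials and therapist labels.

A trial is a time-ordered stream of :class:`SkeletonFrame` samples from a
depth camera using the 25-joint Kinect-v2 layout: per-joint 3D positions in
meters (camera coordinates), per-joint orientation quaternions ``(w, x, y, z)``
and the floor-plane coefficients ``(a, b, c, d)`` of ``ax + by + cz + d = 0``.
Therapist ratings are three-level (good / fair / bad) per assessed aspect.

Frame CSV schema (long format, one row per frame x joint, UTF-8, header
mandatory)::

    trial_id,frame_idx,timestamp,joint,x,y,z,qw,qx,qy,qz,floor_a,floor_b,floor_c,floor_d

Label CSV schema::

    subject_id,trial_id,aspect,rating,rater_id
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "JOINT_ALIASES",
    "ASPECTS",
    "RATINGS",
    "SkeletonFrame",
    "MotionSequence",
    "TherapistLabel",
    "SchemaError",
    "OrderingError",
    "InvariantError",
    "read_motion_csv",
    "write_motion_csv",
    "read_labels_csv",
    "write_labels_csv",
]

#: Canonical 25-joint Kinect-v2 vocabulary.
JOINT_NAMES: tuple[str, ...] = (
    "spine_base", "spine_mid", "neck", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "hip_left", "knee_left", "ankle_left", "foot_left",
    "hip_right", "knee_right", "ankle_right", "foot_right",
    "spine_shoulder", "hand_tip_left", "thumb_left",
    "hand_tip_right", "thumb_right",
)

#: Informal names used in clinical descriptions -> canonical joints.
JOINT_ALIASES: Mapping[str, str] = {
    "shoulder center": "spine_shoulder",
    "shoulder_center": "spine_shoulder",
    "hip center": "spine_base",
    "hip_center": "spine_base",
}

ASPECTS = ("ROM", "coordination", "compensation")
RATINGS = ("good", "fair", "bad")

_RATING_TOKENS = {
    "g": "good", "good": "good",
    "f": "fair", "fair": "fair",
    "b": "bad", "bad": "bad",
}

_QUAT_NORM_TOL = 1e-6
_QUAT_RENORM_TOL = 1e-3


class SchemaError(ValueError):
    """A file does not conform to the expected column/joint schema."""


class OrderingError(ValueError):
    """Timestamps are not strictly increasing / regularly sampled."""


class InvariantError(ValueError):
    """A domain-type invariant is violated."""


def canonical_joint(name: str) -> str:
    """Map an informal joint name to the canonical vocabulary."""
    name = name.strip()
    if name in JOINT_NAMES:
        return name
    key = name.lower()
    if key in JOINT_ALIASES:
        return JOINT_ALIASES[key]
    raise SchemaError(f"unknown joint name: {name!r}")


@dataclass
class SkeletonFrame:
    """One time-stamped skeletal sample.

    Parameters
    ----------
    timestamp : float
        Seconds from trial start.
    joints : dict
        joint name -> position, shape (3,), meters, camera coordinates.
    orientations : dict
        joint name -> unit quaternion (w, x, y, z).
    floor_plane : ndarray, shape (4,)
        Coefficients (a, b, c, d) of the floor plane; (a, b, c) unit norm.
    """

    timestamp: float
    joints: dict[str, np.ndarray]
    orientations: dict[str, np.ndarray]
    floor_plane: np.ndarray

    def validate(self) -> None:
        missing = set(JOINT_NAMES) - set(self.joints)
        if missing:
            raise InvariantError(f"missing joints: {sorted(missing)}")
        extra = set(self.joints) - set(JOINT_NAMES)
        if extra:
            raise InvariantError(f"unknown joints: {sorted(extra)}")
        for name, q in self.orientations.items():
            n = float(np.linalg.norm(q))
            if abs(n - 1.0) > _QUAT_NORM_TOL:
                raise InvariantError(
                    f"quaternion for {name} has norm {n:.6g}, expected 1"
                )
        plane = np.asarray(self.floor_plane, dtype=float)
        if plane.shape != (4,):
            raise InvariantError("floor_plane must have 4 coefficients")
        n = float(np.linalg.norm(plane[:3]))
        if abs(n - 1.0) > _QUAT_NORM_TOL:
            raise InvariantError(f"floor normal has norm {n:.6g}, expected 1")

    def copy(self) -> "SkeletonFrame":
        return SkeletonFrame(
            timestamp=self.timestamp,
            joints={k: np.array(v, dtype=float) for k, v in self.joints.items()},
            orientations={k: np.array(v, dtype=float) for k, v in self.orientations.items()},
            floor_plane=np.array(self.floor_plane, dtype=float),
        )


@dataclass
class MotionSequence:
    """An ordered skeletal trial.

    Invariants: timestamps strictly increasing, inter-frame gaps within 10%
    of ``1/frame_rate``, at least two frames.
    """

    frames: list[SkeletonFrame]
    frame_rate: float = 60.0
    subject_id: str = ""
    exercise_id: str = ""
    trial_id: str = ""

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if len(self.frames) < 2:
            raise InvariantError("a motion sequence needs at least 2 frames")
        ts = self.timestamps
        dt = np.diff(ts)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise OrderingError(
                f"timestamps not strictly increasing at frame {i + 1}"
            )
        nominal = 1.0 / self.frame_rate
        if np.any(np.abs(dt - nominal) > 0.1 * nominal):
            i = int(np.argmax(np.abs(dt - nominal) > 0.1 * nominal))
            raise OrderingError(
                f"frame gap at frame {i + 1} deviates from 1/frame_rate by >10%"
            )
        for f in self.frames:
            if not f.joints:
                raise InvariantError("frame with empty joint map")
            f.validate()

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def positions(self, joint: str) -> np.ndarray:
        """Per-frame positions of one joint, shape (n_frames, 3)."""
        joint = canonical_joint(joint)
        return np.stack([f.joints[joint] for f in self.frames])

    def copy(self) -> "MotionSequence":
        return replace(self, frames=[f.copy() for f in self.frames])


@dataclass(frozen=True)
class TherapistLabel:
    """A single good/fair/bad rating of one aspect of one trial."""

    subject_id: str
    trial_id: str
    aspect: str
    rating: str
    rater_id: str

    def __post_init__(self) -> None:
        if self.rating not in RATINGS:
            raise InvariantError(f"rating must be one of {RATINGS}, got {self.rating!r}")
        if self.aspect not in ASPECTS:
            raise InvariantError(f"aspect must be one of {ASPECTS}, got {self.aspect!r}")


_FRAME_COLUMNS = [
    "trial_id", "frame_idx", "timestamp", "joint",
    "x", "y", "z", "qw", "qx", "qy", "qz",
    "floor_a", "floor_b", "floor_c", "floor_d",
]


def estimate_floor_plane(frame_joints: Mapping[str, np.ndarray]) -> np.ndarray:
    """Fallback floor plane: the horizontal plane through the lower ankle.

    Used when a file carries no floor coefficients; assumes the camera's y
    axis is vertical (a reasonable default for a leveled sensor).
    """
    low = min(frame_joints["ankle_left"][1], frame_joints["ankle_right"][1])
    return np.array([0.0, 1.0, 0.0, -float(low)])


def read_motion_csv(path: str | Path, frame_rate: float = 60.0) -> MotionSequence:
    """Read a long-format frame CSV into a validated :class:`MotionSequence`.

    Quaternions within 1e-3 of unit norm are renormalized; a missing or
    all-NaN floor plane is estimated via :func:`estimate_floor_plane`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in _FRAME_COLUMNS if c not in df.columns and not c.startswith("floor")]
    if missing_cols:
        raise SchemaError(f"{path.name}: missing columns {missing_cols}")
    has_floor = all(c in df.columns for c in ("floor_a", "floor_b", "floor_c", "floor_d"))

    present = set(df["joint"].unique())
    missing_joints = set(JOINT_NAMES) - present
    if missing_joints:
        raise SchemaError(
            f"{path.name}: missing joint column(s) {sorted(missing_joints)}"
        )

    frames: list[SkeletonFrame] = []
    trial_id = str(df["trial_id"].iloc[0])
    last_ts = -np.inf
    for row_offset, (idx, grp) in enumerate(df.groupby("frame_idx", sort=True)):
        ts = float(grp["timestamp"].iloc[0])
        if ts <= last_ts:
            raise OrderingError(
                f"{path.name}: non-monotonic timestamp at data row "
                f"{int(grp.index[0]) + 2} (frame_idx {idx})"
            )
        last_ts = ts
        joints: dict[str, np.ndarray] = {}
        orientations: dict[str, np.ndarray] = {}
        for _, r in grp.iterrows():
            j = canonical_joint(str(r["joint"]))
            joints[j] = np.array([r["x"], r["y"], r["z"]], dtype=float)
            q = np.array([r["qw"], r["qx"], r["qy"], r["qz"]], dtype=float)
            n = float(np.linalg.norm(q))
            if abs(n - 1.0) > _QUAT_NORM_TOL:
                if abs(n - 1.0) <= _QUAT_RENORM_TOL:
                    q = q / n
                else:
                    raise InvariantError(
                        f"{path.name}: quaternion norm {n:.4g} for joint {j} "
                        f"at frame_idx {idx} is not within 1e-3 of 1"
                    )
            orientations[j] = q
        if has_floor and np.isfinite(grp[["floor_a", "floor_b", "floor_c", "floor_d"]].iloc[0]).all():
            plane = grp[["floor_a", "floor_b", "floor_c", "floor_d"]].iloc[0].to_numpy(dtype=float)
        else:
            plane = estimate_floor_plane(joints)
        frames.append(SkeletonFrame(ts, joints, orientations, plane))

    n_rows = len(df)
    if n_rows != len(frames) * len(JOINT_NAMES):
        raise SchemaError(
            f"{path.name}: {n_rows} data rows is not frames x 25 joints"
        )
    seq = MotionSequence(frames=frames, frame_rate=frame_rate, trial_id=trial_id)
    seq.validate()
    return seq


def write_motion_csv(seq: MotionSequence, path: str | Path) -> Path:
    """Write a sequence to the long-format frame CSV; inverse of read.

    The sequence is validated first; the round trip is lossless to better
    than 1e-9 on positions and quaternions (full ``repr`` precision).
    """
    seq.validate()
    path = Path(path)
    rows = []
    for i, f in enumerate(seq.frames):
        for j in JOINT_NAMES:
            p = f.joints[j]
            q = f.orientations.get(j, np.array([1.0, 0.0, 0.0, 0.0]))
            rows.append((
                seq.trial_id, i, f.timestamp, j,
                p[0], p[1], p[2], q[0], q[1], q[2], q[3],
                f.floor_plane[0], f.floor_plane[1], f.floor_plane[2], f.floor_plane[3],
            ))
    df = pd.DataFrame(rows, columns=_FRAME_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_labels_csv(path: str | Path) -> list[TherapistLabel]:
    """Read therapist labels; ratings normalized from {G,F,B} or words."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = ["subject_id", "trial_id", "aspect", "rating", "rater_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    labels = []
    for i, r in df.iterrows():
        token = str(r["rating"]).strip().lower()
        if token not in _RATING_TOKENS:
            raise SchemaError(
                f"{path.name}: unknown rating token {r['rating']!r} at data row {i + 2}"
            )
        labels.append(TherapistLabel(
            subject_id=str(r["subject_id"]).strip(),
            trial_id=str(r["trial_id"]).strip(),
            aspect=str(r["aspect"]).strip(),
            rating=_RATING_TOKENS[token],
            rater_id=str(r["rater_id"]).strip(),
        ))
    return labels


def write_labels_csv(labels: Iterable[TherapistLabel], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(l.subject_id, l.trial_id, l.aspect, l.rating, l.rater_id) for l in labels],
        columns=["subject_id", "trial_id", "aspect", "rating", "rater_id"],
    )
    df.to_csv(path, index=False)
    return path
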