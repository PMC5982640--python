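"""Kinematic feature extraction from skeletal streams.

Raw joint streams are re-expressed in a body-anchored Personal Coordinate
System (PCS) built per frame from the hip line and the floor normal, so that
every feature is invariant to where the subject stands and which way they
face. From the PCS stream the module derives:

* joint angles (cosine law on inter-joint distances), in degrees;
* frontal/sagittal-plane elevation angles (e.g. hip abduction from vertical);
* buffered linear speeds (m/s) - per-frame displacements averaged over a
  sliding buffer of ``buffer_len`` frames (default 15, i.e. 0.25 s at 60 Hz),
  either as magnitudes or signed along one PCS axis;
* buffered angular speeds (deg/s) as the buffered first difference of an
  angle channel;
* per-joint rotations (pitch/yaw/roll) of the orientation quaternion
  relative to parent axes.

Feature sets are declared as :class:`FeatureSpec` lists; the canonical
four-channel hip-abduction vector (hip-center speed, shoulder-center speed,
right-hip frontal angular speed, right-hip frontal angle) ships as
:func:`abduction_preset`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .skeleton import JOINT_NAMES, MotionSequence, canonical_joint

__all__ = [
    "PCSFrame",
    "FeatureSpec",
    "FeatureSeries",
    "DomainError",
    "DegeneratePoseError",
    "ConfigError",
    "angle_from_sides",
    "angle_at_joint",
    "vector_angle",
    "cross_product",
    "build_pcs",
    "to_personal_coords",
    "buffered_speed",
    "default_buffer_len",
    "quaternion_to_rotations",
    "extract_features",
    "abduction_preset",
    "assessment_preset",
]

_AXES = ("lr", "ud", "fb")


class DomainError(ValueError):
    """Geometric input outside the operation's domain."""


class DegeneratePoseError(DomainError):
    """A pose from which the personal coordinate system cannot be built."""


class ConfigError(ValueError):
    """Invalid feature specification."""


# ---------------------------------------------------------------------------
# geometric primitives


def angle_from_sides(a: float, b: float, c: float) -> float:
    """Angle A (degrees) opposite side ``a`` in a triangle with sides a, b, c.

    Cosine law: ``cos A = (-a^2 + b^2 + c^2) / (2bc)``. Degenerate (flat)
    triangles are allowed at the boundary; violations of the triangle
    inequality beyond 1e-9 raise :class:`DomainError`.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise DomainError("triangle sides must be positive")
    cos_a = (-a * a + b * b + c * c) / (2.0 * b * c)
    if abs(cos_a) > 1.0:
        # allow flat triangles within numerical slack
        if abs(cos_a) - 1.0 > 1e-9 * max(1.0, abs(cos_a)):
            raise DomainError(
                f"sides ({a}, {b}, {c}) violate the triangle inequality"
            )
        cos_a = float(np.clip(cos_a, -1.0, 1.0))
    return float(np.degrees(np.arccos(cos_a)))


def angle_at_joint(p_prox: np.ndarray, p_joint: np.ndarray, p_dist: np.ndarray) -> float:
    """Angle (degrees) at ``p_joint`` between the segments to prox and dist.

    Computed from the three inter-point distances via the cosine law; equals
    the angle between the vectors ``p_prox - p_joint`` and ``p_dist - p_joint``.
    """
    p_prox = np.asarray(p_prox, dtype=float)
    p_joint = np.asarray(p_joint, dtype=float)
    p_dist = np.asarray(p_dist, dtype=float)
    a = float(np.linalg.norm(p_prox - p_dist))
    b = float(np.linalg.norm(p_joint - p_prox))
    c = float(np.linalg.norm(p_joint - p_dist))
    if b < 1e-9 or c < 1e-9:
        raise DomainError("coincident points")
    if a < 1e-12:  # prox == dist: zero angle
        return 0.0
    return angle_from_sides(a, b, c)


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors sharing an origin, via the cosine-law path."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return angle_at_joint(u, np.zeros_like(u), v)


def cross_product(u: Sequence[float], v: Sequence[float]) -> np.ndarray:
    """Cross product ``u x v = [u2 v3 - u3 v2, u3 v1 - u1 v3, u1 v2 - u2 v1]``."""
    u1, u2, u3 = float(u[0]), float(u[1]), float(u[2])
    v1, v2, v3 = float(v[0]), float(v[1]), float(v[2])
    return np.array([u2 * v3 - u3 * v2, u3 * v1 - u1 * v3, u1 * v2 - u2 * v1])


# ---------------------------------------------------------------------------
# personal coordinate system


@dataclass
class PCSFrame:
    """Body-anchored frame: origin on the floor below the hip midpoint,
    axes left->right, up, and front/back (right-handed, orthonormal)."""

    origin: np.ndarray
    axis_lr: np.ndarray
    axis_ud: np.ndarray
    axis_fb: np.ndarray

    @property
    def rotation_matrix(self) -> np.ndarray:
        """Columns are (lr, ud, fb) expressed in camera coordinates."""
        return np.column_stack([self.axis_lr, self.axis_ud, self.axis_fb])

    def validate(self) -> None:
        r = self.rotation_matrix
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise DomainError("PCS axes are not orthonormal")
        if np.linalg.det(r) < 0:
            raise DomainError("PCS axes are not right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express camera-coordinate point(s) in (lr, ud, fb) components."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation_matrix


def build_pcs(hip_left: np.ndarray, hip_right: np.ndarray,
              floor_plane: Sequence[float]) -> PCSFrame:
    """Construct the personal coordinate system for one frame.

    The left->right hip vector is projected onto the floor plane to give the
    lateral axis; the floor normal (oriented toward the body) is the vertical
    axis; their cross product closes the right-handed triad. The origin is
    the floor point below the hip midpoint.
    """
    hip_left = np.asarray(hip_left, dtype=float)
    hip_right = np.asarray(hip_right, dtype=float)
    plane = np.asarray(floor_plane, dtype=float)
    n_norm = np.linalg.norm(plane[:3])
    if n_norm < 1e-9:
        raise DomainError("degenerate floor normal")
    n = plane[:3] / n_norm
    d = plane[3] / n_norm
    mid = 0.5 * (hip_left + hip_right)
    if float(n @ mid + d) < 0:  # make the normal point toward the body
        n, d = -n, -d
    lr_raw = hip_right - hip_left
    if np.linalg.norm(lr_raw) < 1e-9:
        raise DegeneratePoseError("hip joints coincide")
    lr_proj = lr_raw - (lr_raw @ n) * n
    if np.linalg.norm(lr_proj) < 1e-8:
        raise DegeneratePoseError("hip line is parallel to the floor normal")
    axis_lr = lr_proj / np.linalg.norm(lr_proj)
    axis_ud = n
    fb = cross_product(axis_lr, axis_ud)
    axis_fb = fb / np.linalg.norm(fb)
    # re-orthogonalize (lr already orthogonal to ud by projection; keep exact)
    axis_lr = cross_product(axis_ud, axis_fb)
    axis_lr /= np.linalg.norm(axis_lr)
    origin = mid - (n @ mid + d) * n
    pcs = PCSFrame(origin=origin, axis_lr=axis_lr, axis_ud=axis_ud, axis_fb=axis_fb)
    pcs.validate()
    return pcs


def sequence_pcs(seq: MotionSequence) -> list[PCSFrame]:
    """Per-frame PCS of a sequence; errors name the offending frame."""
    out = []
    for i, f in enumerate(seq.frames):
        try:
            out.append(build_pcs(f.joints["hip_left"], f.joints["hip_right"], f.floor_plane))
        except DomainError as e:
            raise DegeneratePoseError(f"frame {i}: {e}") from e
    return out


def to_personal_coords(seq: MotionSequence) -> MotionSequence:
    """Re-express every joint position in PCS (lr, ud, fb) components.

    The output is invariant under rigid rotations of the input about the
    floor normal and translations along the floor. Orientation quaternions
    are carried over unchanged (they remain camera-relative); the floor plane
    becomes ``y = 0``.
    """
    pcs_frames = sequence_pcs(seq)
    out = seq.copy()
    for frame, pcs in zip(out.frames, pcs_frames):
        for j, p in frame.joints.items():
            frame.joints[j] = pcs.to_local(p)
        frame.floor_plane = np.array([0.0, 1.0, 0.0, 0.0])
    return out


# ---------------------------------------------------------------------------
# speeds and rotations


def default_buffer_len(frame_rate: float) -> int:
    """The denoising buffer spans 0.25 s: 15 frames at the nominal 60 Hz."""
    return int(round(0.25 * frame_rate))


def buffered_speed(series: np.ndarray, buffer_len: int, frame_rate: float,
                   signed: bool = False,
                   average: str = "velocity") -> np.ndarray:
    """Buffer-averaged speed of a positional series.

    ``series`` is (n,) scalar or (n, d) positional. Per-frame velocities are
    the consecutive differences times ``frame_rate``, averaged over the
    ``buffer_len - 1`` differences spanned by a sliding buffer of
    ``buffer_len`` frames (updated every frame by discarding the oldest
    sample). The first ``buffer_len - 1`` outputs are NaN (buffer not yet
    filled).

    ``average='velocity'`` (default) averages the velocities first and
    reports the magnitude of the average (the buffer then actually denoises:
    jitter cancels); ``average='magnitude'`` averages the per-frame speed
    magnitudes, which preserves a positive jitter floor. ``signed=True``
    (scalar series only) keeps the signed average.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if buffer_len < 2:
        raise ConfigError("buffer_len must be >= 2")
    if average not in ("velocity", "magnitude"):
        raise ConfigError(f"unknown averaging mode {average!r}")
    if n <= buffer_len:
        raise DomainError(f"series of length {n} shorter than buffer {buffer_len}")
    diffs = np.diff(series, axis=0) * frame_rate  # velocity, index i is frame i+1
    w = buffer_len - 1
    kernel = np.ones(w) / w

    def windowed_mean(x: np.ndarray) -> np.ndarray:
        return np.convolve(x, kernel, mode="valid")  # length n - buffer_len + 1

    if series.ndim == 1:
        if signed:
            vals = windowed_mean(diffs)
        elif average == "magnitude":
            vals = windowed_mean(np.abs(diffs))
        else:
            vals = np.abs(windowed_mean(diffs))
    else:
        if signed:
            raise ConfigError("signed speed of a vector series needs a projection axis")
        if average == "magnitude":
            vals = windowed_mean(np.linalg.norm(diffs, axis=1))
        else:
            vals = np.linalg.norm(
                np.stack([windowed_mean(diffs[:, j]) for j in range(series.shape[1])],
                         axis=1), axis=1)
    out = np.full(n, np.nan)
    out[buffer_len - 1:] = vals
    return out


def quaternion_to_rotations(q: Sequence[float],
                            parent_axes: PCSFrame | np.ndarray | None = None
                            ) -> tuple[tuple[float, float, float], bool]:
    """Intrinsic (pitch, yaw, roll) of a joint quaternion w.r.t. parent axes.

    ``q`` is (w, x, y, z) with unit norm. Returns the intrinsic x-y-z Euler
    angles in degrees of the joint frame expressed in ``parent_axes`` (a
    :class:`PCSFrame`, a 3x3 axis matrix, or None for camera axes), plus a
    gimbal-lock flag; at lock the canonical (yaw-absorbing) decomposition is
    returned.
    """
    q = np.asarray(q, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise DomainError("quaternion is not unit norm")
    rot = Rotation.from_quat(q, scalar_first=True).as_matrix()
    if parent_axes is not None:
        p = parent_axes.rotation_matrix if isinstance(parent_axes, PCSFrame) else np.asarray(parent_axes, dtype=float)
        rot = p.T @ rot
    lock = bool(abs(rot[0, 2]) >= 1.0 - 1e-9)  # sin(middle angle) at +-1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pitch, yaw, roll = Rotation.from_matrix(rot).as_euler("XYZ", degrees=True)
    return (float(pitch), float(yaw), float(roll)), lock


# ---------------------------------------------------------------------------
# feature specification and extraction


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of one feature channel.

    kind:
        ``joint_angle``     args: joints=[prox, joint, dist] (interior angle)
                            or joints=[pivot, distal], plane='frontal'|'sagittal'
                            (elevation from the downward vertical in that plane)
        ``pcs_position``    args: joint=..., axis='lr'|'ud'|'fb'
        ``buffered_speed``  args: joint=..., optional signed_axis='lr'|'ud'|'fb'
        ``angular_speed``   args: source=<angle feature name>
        ``rotation``        args: joint=..., component='pitch'|'yaw'|'roll'
    """

    name: str
    kind: str
    arguments: Mapping[str, object] = field(default_factory=dict)
    buffer_len: int | None = None  # None: round(0.25 * frame_rate)

    def __post_init__(self):
        kinds = ("joint_angle", "pcs_position", "buffered_speed", "angular_speed", "rotation")
        if self.kind not in kinds:
            raise ConfigError(f"unknown feature kind {self.kind!r}")
        object.__setattr__(self, "arguments", dict(self.arguments))

    @property
    def directional_axis(self) -> str | None:
        """PCS axis along which this channel is signed, if any."""
        ax = self.arguments.get("signed_axis")
        return str(ax) if ax is not None else None

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind,
                "arguments": dict(self.arguments), "buffer_len": self.buffer_len}

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FeatureSpec":
        return cls(name=str(d["name"]), kind=str(d["kind"]),
                   arguments=dict(d.get("arguments", {})),
                   buffer_len=d.get("buffer_len"))


@dataclass
class FeatureSeries:
    """Named per-frame feature channels for one trial.

    ``values`` is (n_frames, n_features); buffered-speed channels are NaN
    before ``valid_from`` (the first frame with a full buffer).
    ``directional`` maps channel name -> PCS axis for signed channels.
    """

    feature_names: list[str]
    values: np.ndarray
    frame_rate: float
    valid_from: int = 0
    timestamps: np.ndarray | None = None
    directional: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ConfigError("values must be (n_frames, n_features)")

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def matrix(self, names: Sequence[str] | None = None, valid_only: bool = True) -> np.ndarray:
        """Observation matrix for the given channels (all, by default)."""
        names = list(names) if names is not None else self.feature_names
        idx = [self.feature_names.index(n) for n in names]
        m = self.values[:, idx]
        return m[self.valid_from:] if valid_only else m

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        ts = self.timestamps if self.timestamps is not None else \
            np.arange(len(self)) / self.frame_rate
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "timestamp", ts)
        df.insert(0, "frame_idx", np.arange(len(self)))
        df.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate: float = 60.0) -> "FeatureSeries":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("frame_idx", "timestamp")]
        values = df[names].to_numpy(dtype=float)
        nan_rows = np.isnan(values).any(axis=1)
        valid_from = int(np.argmin(nan_rows)) if nan_rows.any() else 0
        if nan_rows.all():
            valid_from = len(values)
        return cls(feature_names=names, values=values, frame_rate=frame_rate,
                   valid_from=valid_from,
                   timestamps=df["timestamp"].to_numpy(dtype=float))


def abduction_preset() -> list[FeatureSpec]:
    """The canonical four-channel hip-abduction feature vector.

    F0 hip-center speed (m/s), F1 shoulder-center speed (m/s), F2 right hip
    frontal angular speed (deg/s, signed), F3 right hip frontal angle (deg).
    """
    return [
        FeatureSpec("hip_center_speed", "buffered_speed", {"joint": "spine_base"}),
        FeatureSpec("shoulder_center_speed", "buffered_speed", {"joint": "spine_shoulder"}),
        FeatureSpec("hip_right_frontal_speed", "angular_speed",
                    {"source": "hip_right_frontal_angle"}),
        FeatureSpec("hip_right_frontal_angle", "joint_angle",
                    {"joints": ["hip_right", "knee_right"], "plane": "frontal"}),
    ]


def assessment_preset() -> list[FeatureSpec]:
    """Abduction preset plus the signed lateral-speed channels used for
    movement clipping and error-direction analysis.

    The personal coordinate system is anchored on the hips, so a lateral
    drift of the pelvis itself is only observable relative to the support:
    the signed channels therefore measure motion relative to the stance
    (left) ankle, which stays planted during right-leg exercises.
    """
    stance = ["ankle_left"]
    return abduction_preset() + [
        FeatureSpec("shoulder_center_lr_speed", "buffered_speed",
                    {"joint": "spine_shoulder", "signed_axis": "lr",
                     "relative_to": stance}),
        FeatureSpec("pelvis_lr_speed", "buffered_speed",
                    {"joint": "spine_base", "signed_axis": "lr",
                     "relative_to": stance}),
    ]


def extract_features(seq: MotionSequence, specs: Sequence[FeatureSpec],
                     buffer_len: int | None = None) -> FeatureSeries:
    """Evaluate a list of feature specs on a motion sequence.

    Angles are in degrees, angular speeds in deg/s, linear speeds in m/s.
    Channels are evaluated in dependency order (``angular_speed`` may name
    any angle channel in the same list). Deterministic: identical inputs
    give bit-identical outputs.
    """
    seq.validate()
    n = len(seq)
    fps = seq.frame_rate
    bl = buffer_len if buffer_len is not None else default_buffer_len(fps)
    pcs_frames = sequence_pcs(seq)
    # PCS positions per joint, (n, 3) in (lr, ud, fb) components
    local: dict[str, np.ndarray] = {}

    def local_pos(joint: str) -> np.ndarray:
        joint = canonical_joint(joint)
        if joint not in local:
            raw = seq.positions(joint)
            local[joint] = np.stack([pcs.to_local(p) for pcs, p in zip(pcs_frames, raw)])
        return local[joint]

    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate feature names")
    columns: dict[str, np.ndarray] = {}
    directional: dict[str, str | None] = {}
    has_speed = False

    def eval_spec(spec: FeatureSpec) -> np.ndarray:
        nonlocal has_speed
        args = spec.arguments
        this_bl = spec.buffer_len or bl
        if spec.kind == "joint_angle":
            joints = [canonical_joint(j) for j in args["joints"]]
            plane = args.get("plane")
            if plane is None:
                if len(joints) != 3:
                    raise ConfigError("interior joint_angle needs 3 joints")
                prox, mid, dist = (local_pos(j) for j in joints)
                return np.array([angle_at_joint(prox[i], mid[i], dist[i]) for i in range(n)])
            if len(joints) != 2:
                raise ConfigError("planar joint_angle needs [pivot, distal]")
            if plane not in ("frontal", "sagittal"):
                raise ConfigError(f"unknown plane {plane!r}")
            pivot, distal = local_pos(joints[0]), local_pos(joints[1])
            v = distal - pivot
            keep = (0, 1) if plane == "frontal" else (2, 1)  # (lateral|fb, vertical)
            down = np.array([0.0, -1.0, 0.0])
            out = np.empty(n)
            for i in range(n):
                vp = np.zeros(3)
                vp[keep[0]] = v[i, keep[0]]
                vp[1] = v[i, 1]
                out[i] = vector_angle(vp, down)
            return out
        if spec.kind == "pcs_position":
            axis = str(args.get("axis", "lr"))
            return local_pos(str(args["joint"]))[:, _AXES.index(axis)]
        if spec.kind == "buffered_speed":
            has_speed = True
            pos = local_pos(str(args["joint"]))
            rel = args.get("relative_to")
            if rel:  # speed relative to a reference joint (or joint-set midpoint)
                ref = [rel] if isinstance(rel, str) else list(rel)
                pos = pos - np.mean([local_pos(r) for r in ref], axis=0)
            axis = args.get("signed_axis")
            if axis is None:
                return buffered_speed(pos, this_bl, fps)
            directional[spec.name] = str(axis)
            return buffered_speed(pos[:, _AXES.index(str(axis))], this_bl, fps, signed=True)
        if spec.kind == "angular_speed":
            has_speed = True
            src = str(args["source"])
            if src not in columns:
                raise ConfigError(f"angular_speed source {src!r} not computed")
            directional[spec.name] = None
            return buffered_speed(columns[src], this_bl, fps, signed=True)
        if spec.kind == "rotation":
            joint = canonical_joint(str(args["joint"]))
            comp = ("pitch", "yaw", "roll").index(str(args.get("component", "pitch")))
            out = np.empty(n)
            for i, (frame, pcs) in enumerate(zip(seq.frames, pcs_frames)):
                angles, _ = quaternion_to_rotations(frame.orientations[joint], pcs)
                out[i] = angles[comp]
            return out
        raise ConfigError(f"unknown feature kind {spec.kind!r}")

    # two passes: independent channels first, then derived (angular_speed)
    for spec in specs:
        if spec.kind != "angular_speed":
            columns[spec.name] = eval_spec(spec)
            directional.setdefault(spec.name, None)
    for spec in specs:
        if spec.kind == "angular_speed":
            columns[spec.name] = eval_spec(spec)
    values = np.column_stack([columns[name] for name in names])
    valid_from = (bl - 1) if has_speed else 0
    return FeatureSeries(feature_names=names, values=values, frame_rate=fps,
                         valid_from=valid_from, timestamps=seq.timestamps,
                         directional=directional)


def load_feature_specs(path: str | Path) -> list[FeatureSpec]:
    """Read a FeatureSpec list from a JSON config file."""
    with open(path) as fh:
        data = json.load(fh)
    return [FeatureSpec.from_dict(d) for d in data]


def save_feature_specs(specs: Iterable[FeatureSpec], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh, indent=2)
    return path
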