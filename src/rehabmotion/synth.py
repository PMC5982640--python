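"""Seeded generator of skeletal hip-abduction trials with injectable faults.

No recorded patient data ships with the package, so this module emulates the
canonical exercise: a standing subject laterally raises the right leg
(rest -> rise -> hold -> return -> rest) while the trunk counter-sways. The
abduction angle follows a raised-cosine profile (smooth, zero end-velocity);
the shoulder-center sway tracks the angle profile, producing the twin speed
bumps on rise and fall that the trunk model is trained on.

Injectable faults mirror common compensations:

* ``trunk_shift``  - trunk sway advanced/delayed vs the leg (incoordination);
* ``asymmetry``    - return slower/faster than the raise (uneven effort);
* ``wobble``       - transient lateral jolt mid-hold (balance loss, the
  "extra bump" signature);
* ``end_drift``    - pelvis drifts left relative to the feet at the end of
  the movement (adduction compensation of the contralateral hip);
* ``reduced_rom``  - peak abduction scaled down.

Measurement noise is band-limited (moving-average-filtered white noise with
stationary sd ``noise_sd``), approximating the temporally correlated jitter
of skeletal tracking; frame-independent noise at realistic amplitude would
dominate finite-difference speeds in a way real tracking does not.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import json
import numpy as np
from scipy.ndimage import uniform_filter1d

from .skeleton import (
    JOINT_NAMES, MotionSequence, SkeletonFrame, TherapistLabel,
    write_labels_csv, write_motion_csv,
)

__all__ = [
    "SyntheticMotionSpec",
    "SyntheticTruth",
    "CohortTrial",
    "Cohort",
    "FAULT_KINDS",
    "simulate_abduction",
    "inject_faults",
    "generate_cohort",
]

FAULT_KINDS = ("trunk_shift", "asymmetry", "wobble", "end_drift", "reduced_rom")

#: Default fault magnitudes (the stated world; see docs/methods.md).
DEFAULT_FAULT_MAGNITUDES = {
    "trunk_shift": 30.0,   # frames
    "asymmetry": 1.5,      # fall/rise duration multiplier
    "wobble": 0.04,        # m, lateral jolt amplitude
    "end_drift": 0.06,     # m, pelvis lateral drift
    "reduced_rom": 0.5,    # peak-angle factor
}

_NOISE_SMOOTH = 15  # frames of moving-average smoothing for positional noise

# standing template, meters; subject at z = 2.5 facing the camera,
# floor y = 0, left = -x, right = +x
_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "spine_base": (0.0, 1.00, 2.5),
    "spine_mid": (0.0, 1.25, 2.5),
    "spine_shoulder": (0.0, 1.50, 2.5),
    "neck": (0.0, 1.57, 2.5),
    "head": (0.0, 1.72, 2.5),
    "shoulder_left": (-0.20, 1.45, 2.5),
    "elbow_left": (-0.25, 1.18, 2.5),
    "wrist_left": (-0.27, 0.95, 2.5),
    "hand_left": (-0.28, 0.88, 2.5),
    "hand_tip_left": (-0.28, 0.80, 2.5),
    "thumb_left": (-0.25, 0.90, 2.5),
    "shoulder_right": (0.20, 1.45, 2.5),
    "elbow_right": (0.25, 1.18, 2.5),
    "wrist_right": (0.27, 0.95, 2.5),
    "hand_right": (0.28, 0.88, 2.5),
    "hand_tip_right": (0.28, 0.80, 2.5),
    "thumb_right": (0.25, 0.90, 2.5),
    "hip_left": (-0.09, 0.95, 2.5),
    "knee_left": (-0.09, 0.50, 2.5),
    "ankle_left": (-0.09, 0.08, 2.5),
    "foot_left": (-0.09, 0.03, 2.38),
    "hip_right": (0.09, 0.95, 2.5),
    "knee_right": (0.09, 0.50, 2.5),
    "ankle_right": (0.09, 0.08, 2.5),
    "foot_right": (0.09, 0.03, 2.38),
}

_UPPER_BODY = (
    "spine_mid", "spine_shoulder", "neck", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "hand_tip_left", "thumb_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "hand_tip_right", "thumb_right",
)
_RIGHT_LEG = ("knee_right", "ankle_right", "foot_right")
_PELVIS_AND_UP = _UPPER_BODY + ("spine_base", "hip_left", "hip_right")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class SyntheticMotionSpec:
    """Parameters of one simulated hip-abduction trial.

    Durations are frames at ``frame_rate``; defaults give a 6 s trial at
    60 Hz (1 s rest, 1.5 s raise, 1 s hold, 1.5 s return, 1 s rest) peaking
    at 40 deg of abduction.
    """

    frame_rate: float = 60.0
    rest_before: int = 60
    rise: int = 90
    hold: int = 60
    fall: int = 90
    rest_after: int = 60
    peak_abduction: float = 40.0
    rom_factor: float = 1.0           # reduced-ROM fault: scales peak_abduction
    trunk_coupling: float = 0.03      # m, shoulder-center counter-sway amplitude
    trunk_shift: int = 0              # frames; + = trunk delayed, - = advanced
    asymmetry: float = 1.0            # fall duration multiplier
    wobble_at: tuple[int, float] | None = None   # (frame index, amplitude m)
    end_drift: float = 0.0            # m, pelvis lateral drift (to the left)
    noise_sd: float = 0.002           # m, stationary positional noise
    seed: int = 0

    def validate(self) -> None:
        buf = int(round(0.25 * self.frame_rate))
        for name in ("rest_before", "rise", "hold", "fall", "rest_after"):
            if getattr(self, name) < buf:
                raise ConfigError(f"{name} must be >= buffer length ({buf} frames)")
        if not (0.0 < self.peak_abduction * self.rom_factor < 90.0):
            raise ConfigError("peak abduction must land in (0, 90) degrees")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.asymmetry <= 0:
            raise ConfigError("asymmetry must be > 0")

    @property
    def fall_frames(self) -> int:
        return int(round(self.asymmetry * self.fall))

    @property
    def n_frames(self) -> int:
        return (self.rest_before + self.rise + self.hold
                + self.fall_frames + self.rest_after)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated trial (generator bookkeeping)."""

    phase: np.ndarray               # per-frame 0 rest / 1 rise / 2 hold / 3 fall
    peak_frame: int                 # center of the hold phase
    faults: list[str]
    rise_frames: int
    fall_frames: int


def _unit_profile(spec: SyntheticMotionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine abduction profile in [0, 1] and per-frame phase labels."""
    rb, ri, ho, fa, ra = (spec.rest_before, spec.rise, spec.hold,
                          spec.fall_frames, spec.rest_after)
    u = np.zeros(spec.n_frames)
    phase = np.zeros(spec.n_frames, dtype=np.int64)
    t = np.arange(ri) / ri
    u[rb:rb + ri] = 0.5 * (1.0 - np.cos(np.pi * t))
    phase[rb:rb + ri] = 1
    u[rb + ri:rb + ri + ho] = 1.0
    phase[rb + ri:rb + ri + ho] = 2
    t = np.arange(fa) / fa
    u[rb + ri + ho:rb + ri + ho + fa] = 0.5 * (1.0 + np.cos(np.pi * t))
    phase[rb + ri + ho:rb + ri + ho + fa] = 3
    return u, phase


def _shift(series: np.ndarray, frames: int) -> np.ndarray:
    """Shift a series in time, padding with its edge values."""
    if frames == 0:
        return series
    out = np.empty_like(series)
    if frames > 0:
        out[:frames] = series[0]
        out[frames:] = series[:-frames]
    else:
        out[frames:] = series[-1]
        out[:frames] = series[-frames:]
    return out


def simulate_abduction(spec: SyntheticMotionSpec
                       ) -> tuple[MotionSequence, SyntheticTruth]:
    """Generate one hip-abduction trial and its ground truth."""
    spec.validate()
    n = spec.n_frames
    fps = spec.frame_rate
    u, phase = _unit_profile(spec)
    theta = np.radians(spec.peak_abduction * spec.rom_factor) * u

    # trunk counter-sway (to the left as the right leg abducts), possibly
    # time-shifted; a wobble adds a transient lateral jolt
    sway = -spec.trunk_coupling * _shift(u, spec.trunk_shift)
    faults = []
    if abs(spec.rom_factor - 1.0) > 1e-12:
        faults.append("reduced_rom")
    if spec.trunk_shift != 0:
        faults.append("trunk_shift")
    if abs(spec.asymmetry - 1.0) > 1e-12:
        faults.append("asymmetry")
    if spec.wobble_at is not None:
        frame, amp = spec.wobble_at
        tt = np.arange(n, dtype=float)
        sway = sway + amp * np.exp(-0.5 * ((tt - frame) / 8.0) ** 2)
        faults.append("wobble")
    # pelvis drift to the left ramping up over the return phase
    drift = np.zeros(n)
    if spec.end_drift != 0.0:
        fa_start = spec.rest_before + spec.rise + spec.hold
        fa = spec.fall_frames
        t = np.arange(fa) / fa
        drift[fa_start:fa_start + fa] = 0.5 * (1.0 - np.cos(np.pi * t))
        drift[fa_start + fa:] = 1.0
        drift *= -spec.end_drift
        faults.append("end_drift")

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((n, len(JOINT_NAMES), 3))
    noise = (uniform_filter1d(white, size=_NOISE_SMOOTH, axis=0, mode="nearest")
             * spec.noise_sd * np.sqrt(_NOISE_SMOOTH)) if spec.noise_sd > 0 else \
        np.zeros_like(white)

    hip_r = np.array(_TEMPLATE["hip_right"])
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    frames: list[SkeletonFrame] = []
    ident = np.array([1.0, 0.0, 0.0, 0.0])
    leg_quat = np.column_stack(
        [np.cos(theta / 2), np.zeros(n), np.zeros(n), np.sin(theta / 2)])
    for i in range(n):
        joints: dict[str, np.ndarray] = {}
        orientations: dict[str, np.ndarray] = {}
        for k, name in enumerate(JOINT_NAMES):
            p = np.array(_TEMPLATE[name])
            if name in _RIGHT_LEG:
                # rotate about the hip in the frontal (x-y) plane, outward
                rel = p - hip_r
                x = cos_t[i] * rel[0] - sin_t[i] * rel[1]
                y = sin_t[i] * rel[0] + cos_t[i] * rel[1]
                p = hip_r + np.array([x, y, rel[2]])
            if name in _UPPER_BODY:
                p[0] += sway[i]
            if name in _PELVIS_AND_UP:
                p[0] += drift[i]
            joints[name] = p + noise[i, k]
            orientations[name] = leg_quat[i] if name in ("hip_right", "knee_right") else ident
        frames.append(SkeletonFrame(
            timestamp=i / fps, joints=joints, orientations=orientations,
            floor_plane=np.array([0.0, 1.0, 0.0, 0.0])))

    seq = MotionSequence(frames=frames, frame_rate=fps)
    truth = SyntheticTruth(
        phase=phase,
        peak_frame=spec.rest_before + spec.rise + spec.hold // 2,
        faults=faults,
        rise_frames=spec.rise,
        fall_frames=spec.fall_frames,
    )
    return seq, truth


def inject_faults(spec: SyntheticMotionSpec,
                  faults: Sequence[tuple[str, float]]) -> SyntheticMotionSpec:
    """Return a spec with the given (kind, magnitude) faults set; composable."""
    for kind, magnitude in faults:
        if kind == "trunk_shift":
            spec = replace(spec, trunk_shift=int(round(magnitude)))
        elif kind == "asymmetry":
            spec = replace(spec, asymmetry=float(magnitude))
        elif kind == "wobble":
            mid = spec.rest_before + spec.rise + spec.hold // 2
            spec = replace(spec, wobble_at=(mid, float(magnitude)))
        elif kind == "end_drift":
            spec = replace(spec, end_drift=float(magnitude))
        elif kind == "reduced_rom":
            spec = replace(spec, rom_factor=spec.rom_factor * float(magnitude))
        else:
            raise ConfigError(f"unknown fault kind {kind!r}")
    return spec


@dataclass
class CohortTrial:
    sequence: MotionSequence
    truth: SyntheticTruth
    subject_id: str
    trial_id: str
    exercise_id: str = "hip_abduction"


@dataclass
class Cohort:
    trials: list[CohortTrial]
    labels: list[TherapistLabel]

    def __len__(self) -> int:
        return len(self.trials)

    def write(self, directory: str | Path) -> Path:
        """Emit frame CSVs, a label CSV and a truth JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        truth_blob = {}
        for t in self.trials:
            stem = f"{t.subject_id}_{t.exercise_id}_{t.trial_id}"
            t.sequence.subject_id = t.subject_id
            t.sequence.exercise_id = t.exercise_id
            t.sequence.trial_id = t.trial_id
            write_motion_csv(t.sequence, directory / f"{stem}.csv")
            truth_blob[stem] = {
                "phase": t.truth.phase.tolist(),
                "peak_frame": int(t.truth.peak_frame),
                "faults": list(t.truth.faults),
                "rise_frames": int(t.truth.rise_frames),
                "fall_frames": int(t.truth.fall_frames),
            }
        write_labels_csv(self.labels, directory / "labels.csv")
        with open(directory / "truth.json", "w") as fh:
            json.dump(truth_blob, fh)
        return directory


def _auto_labels(subject_id: str, trial_id: str, fault: tuple[str, float] | None
                 ) -> list[TherapistLabel]:
    """Auto-generated ratings: the faulted aspect drops to fair/bad by
    magnitude; everything else is good."""
    ratings = {"ROM": "good", "coordination": "good", "compensation": "good"}
    if fault is not None:
        kind, mag = fault
        if kind == "reduced_rom":
            ratings["ROM"] = "bad" if mag <= 0.6 else "fair"
        elif kind == "trunk_shift":
            ratings["coordination"] = "bad" if abs(mag) >= 20 else "fair"
        elif kind == "asymmetry":
            ratings["compensation"] = "bad" if abs(mag - 1.0) >= 0.4 else "fair"
        elif kind == "wobble":
            ratings["compensation"] = "bad" if mag >= 0.03 else "fair"
        elif kind == "end_drift":
            ratings["compensation"] = "bad" if mag >= 0.05 else "fair"
    return [TherapistLabel(subject_id, trial_id, aspect, rating, "auto")
            for aspect, rating in ratings.items()]


def generate_cohort(n_subjects: int, trials_per_subject: int,
                    fault_rate: float = 0.25, seed: int = 0,
                    exercises: Sequence[str] = ("hip_abduction",),
                    frame_rate: float = 60.0,
                    fault_magnitudes: dict[str, float] | None = None) -> Cohort:
    """Generate a labelled cohort of simulated trials.

    Each subject gets random kinematic idiosyncrasies (tempo, amplitude,
    sway); ``fault_rate`` of all trials receive one random fault at its
    default magnitude. Deterministic per seed. The number of recordings is
    ``n_subjects * len(exercises) * trials_per_subject``.
    """
    if n_subjects < 2:
        raise ConfigError("a cohort needs at least 2 subjects")
    magnitudes = dict(DEFAULT_FAULT_MAGNITUDES)
    if fault_magnitudes:
        magnitudes.update(fault_magnitudes)
    rng = np.random.default_rng(seed)
    total = n_subjects * len(exercises) * trials_per_subject
    n_fault = int(round(fault_rate * total))
    faulted = set(rng.choice(total, size=n_fault, replace=False).tolist())

    trials: list[CohortTrial] = []
    labels: list[TherapistLabel] = []
    flat_idx = 0
    for s in range(n_subjects):
        subject_id = f"s{s + 1}"
        tempo = rng.uniform(0.85, 1.15)
        peak = float(np.clip(rng.normal(40.0, 3.0), 25.0, 55.0))
        coupling = rng.uniform(0.02, 0.04)
        rest_base = 60 * rng.uniform(0.9, 1.1)
        for exercise_id in exercises:
            for t in range(trials_per_subject):
                trial_id = f"t{t + 1}" if len(exercises) == 1 \
                    else f"{exercise_id}_t{t + 1}"
                jit = rng.uniform(0.95, 1.05, size=4)
                spec = SyntheticMotionSpec(
                    frame_rate=frame_rate,
                    rest_before=int(round(rest_base * jit[0])),
                    rise=int(round(90 * tempo * jit[1])),
                    hold=int(round(60 * tempo * jit[2])),
                    fall=int(round(90 * tempo * jit[1])),
                    rest_after=int(round(rest_base * jit[3])),
                    peak_abduction=peak * rng.uniform(0.97, 1.03),
                    trunk_coupling=coupling,
                    noise_sd=0.002,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                fault: tuple[str, float] | None = None
                if flat_idx in faulted:
                    kind = FAULT_KINDS[int(rng.integers(0, len(FAULT_KINDS)))]
                    mag = magnitudes[kind]
                    if kind == "trunk_shift" and rng.random() < 0.5:
                        mag = -mag
                    fault = (kind, float(mag))
                    spec = inject_faults(spec, [fault])
                seq, truth = simulate_abduction(spec)
                seq.subject_id = subject_id
                seq.exercise_id = exercise_id
                seq.trial_id = trial_id
                trials.append(CohortTrial(seq, truth, subject_id, trial_id, exercise_id))
                labels.extend(_auto_labels(subject_id, trial_id, fault))
                flat_idx += 1
    return Cohort(trials=trials, labels=labels)
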