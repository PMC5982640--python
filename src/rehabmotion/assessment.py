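"""Multi-HMM movement assessment: sliding-window likelihoods, state-path
anomaly detection, symmetry / synchronicity ratios, error direction and
good/fair/bad aggregation.

The blueprint runs a registry of phase HMMs, each bound to its own feature
subset, over one trial:

* per-window forward log-likelihoods (per-frame normalized) localize where
  a trial stops looking like a correct execution;
* the Viterbi state path is compared against a reference profile of state
  visit counts and durations learned from correct executions — missing,
  added, elongated or shortened states flag compensations;
* the movement is clipped between the terminations of the rest state; the
  symmetry ratio compares time-to-peak with time-to-return, and the
  synchronicity ratio compares the trunk clip against the midpoint of the
  hip model's hold state (< 1 means the trunk moved before the hip);
* for models with directional (signed) speed features, low-likelihood
  windows are attributed a direction (left/right/up/down/front/back) by
  comparing observed means against the decoded state's emission means;
* flags and window likelihoods aggregate into a single good / fair / bad
  outcome against thresholds stored with each trained model.

Training is leave-one-subject-out: each subject's registry is fitted on the
correct trials (by therapist-label consensus) of all other subjects.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import ConfigError, FeatureSeries, FeatureSpec, assessment_preset
from .hmm import (GaussianHMM, VARIANCE_FLOOR, ViterbiPath, baum_welch_fit,
                  forward_loglik, viterbi_path)
from .skeleton import ASPECTS, TherapistLabel

__all__ = [
    "AssessConfig",
    "WindowLikelihoodTrace",
    "MovementClipping",
    "AssessmentFlag",
    "MovementAssessment",
    "TrainingStats",
    "RegistryEntry",
    "ModelRegistry",
    "NoMovementError",
    "IncoordinationError",
    "UnsupportedModelError",
    "sliding_window_likelihood",
    "run_length_encode",
    "smooth_path",
    "clip_movement",
    "symmetry_ratio",
    "synchronicity_ratio",
    "report_ratio",
    "build_reference_profile",
    "detect_transition_anomalies",
    "error_direction",
    "classify_movement",
    "aggregate_outcome",
    "correct_trials",
    "loso_train",
    "canonical_registry",
]

OUTCOMES = ("bad", "fair", "good")

_DIRECTION_LABELS = {
    ("lr", -1): "left", ("lr", 1): "right",
    ("ud", -1): "down", ("ud", 1): "up",
    ("fb", -1): "back", ("fb", 1): "front",
}


class NoMovementError(ValueError):
    """The state path contains no non-rest segment."""


class IncoordinationError(ValueError):
    """The hip path has no hold-state segment; no ratio can be formed."""


class UnsupportedModelError(ValueError):
    """The model has no directional-speed features."""


@dataclass(frozen=True)
class AssessConfig:
    """Tunable assessment settings (all defaults documented in the methods
    note)."""

    window_len: int = 60          # frames (~1 s)
    stride: int = 15              # frames
    good_percentile: float = 25.0  # of training per-trial minimum window loglik
    fair_percentile: float = 5.0
    ratio_threshold: float = 0.7   # normalized trunk-hip timing flag level
    symmetry_threshold: float = 0.8  # normalized profile-symmetry flag level
    min_segment: int = 15         # frames (0.25 s); shorter Viterbi runs are smoothed away
    duration_pad: float = 0.25    # slack around reference duration ranges
    var_floor_frac: float = 0.1   # decode-time variance floor (fraction of signal variance)
    rest_state: int = 0
    hold_state: int = 2
    label_majority: float = 0.5   # fraction of raters that must rate good


@dataclass
class WindowLikelihoodTrace:
    """Per-window, per-frame-normalized forward log-likelihoods."""

    window_starts: np.ndarray
    window_len: int
    stride: int
    values: np.ndarray

    @property
    def min_index(self) -> int:
        """Window index of the likelihood minimum (the error locus)."""
        return int(np.argmin(self.values))

    @property
    def min_value(self) -> float:
        return float(np.min(self.values))


@dataclass
class MovementClipping:
    """Movement delimiters: rest-state terminations and the amplitude peak."""

    start_frame: int
    peak_frame: int
    end_frame: int

    def __post_init__(self):
        if not (self.start_frame < self.peak_frame < self.end_frame):
            raise NoMovementError(
                f"degenerate clip ({self.start_frame}, {self.peak_frame}, "
                f"{self.end_frame})")


@dataclass(frozen=True)
class AssessmentFlag:
    """One detected anomaly."""

    model_id: str
    kind: str                      # low_likelihood, extra_transition, ...
    state: int | None = None
    window_index: int | None = None
    direction: str | None = None
    detail: str = ""


@dataclass
class MovementAssessment:
    """Full per-trial result of the multi-HMM blueprint."""

    per_model: dict[str, dict]
    symmetry: float | None
    synchronicity: float | None
    compensation_flags: list[AssessmentFlag]
    outcome: str

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "symmetry": self.symmetry,
            "synchronicity": self.synchronicity,
            "flags": [asdict(f) for f in self.compensation_flags],
            "per_model": {},
        }
        for mid, res in self.per_model.items():
            trace: WindowLikelihoodTrace = res["trace"]
            path: ViterbiPath = res["viterbi"]
            out["per_model"][mid] = {
                "total_loglik": res["total_loglik"],
                "window_starts": trace.window_starts.tolist(),
                "window_len": trace.window_len,
                "stride": trace.stride,
                "window_values": trace.values.tolist(),
                "viterbi_rle": [[int(s), int(l)] for s, _, l in
                                run_length_encode(path.states)],
                "log_joint": path.log_joint,
            }
        return out


# ---------------------------------------------------------------------------
# window likelihoods and state-path utilities


def sliding_window_likelihood(model: GaussianHMM, features,
                              window_len: int = 60, stride: int = 15
                              ) -> WindowLikelihoodTrace:
    """Forward log-likelihood of each sliding window, per-frame normalized."""
    if window_len < 2:
        raise ConfigError("window_len must be >= 2")
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    obs = features.matrix(model.feature_names) if isinstance(features, FeatureSeries) \
        else np.asarray(features, dtype=float)
    n = obs.shape[0]
    if n < window_len:
        raise ValueError(f"sequence of {n} frames shorter than window {window_len}")
    starts = np.arange(0, n - window_len + 1, stride)
    values = np.array([
        forward_loglik(model, obs[s:s + window_len]) / window_len for s in starts
    ])
    return WindowLikelihoodTrace(window_starts=starts, window_len=window_len,
                                 stride=stride, values=values)


def run_length_encode(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Segments of a state path as (state, start, length) triples."""
    states = np.asarray(states)
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    return [(int(states[bounds[i]]), int(bounds[i]), int(bounds[i + 1] - bounds[i]))
            for i in range(len(bounds) - 1)]


def smooth_path(states: np.ndarray, min_segment: int = 5) -> np.ndarray:
    """Absorb Viterbi runs shorter than ``min_segment`` into their left
    neighbour (the first run is absorbed rightward), denoising sporadic
    single-frame state flips before transition analysis."""
    states = np.asarray(states).copy()
    if min_segment <= 1:
        return states
    changed = True
    while changed:
        changed = False
        runs = run_length_encode(states)
        if len(runs) <= 1:
            break
        for i, (s, start, length) in enumerate(runs):
            if length < min_segment:
                target = runs[i - 1][0] if i > 0 else runs[i + 1][0]
                states[start:start + length] = target
                changed = True
                break
    return states


# ---------------------------------------------------------------------------
# clipping and ratios


def clip_movement(trunk_speed: np.ndarray, path: np.ndarray | ViterbiPath,
                  rest_state: int = 0) -> MovementClipping:
    """Delimit the movement and locate its amplitude peak.

    A movement with an out-and-back trunk sway produces two opposite-signed
    speed bumps (on the raise and on the return). The bump extrema are the
    highest-SNR landmarks in the signal, so the clip is anchored on them:
    each bump's half-amplitude width ``w`` recovers its phase duration
    (``d = 1.5 w`` for a raised-cosine displacement profile, whose speed is
    a half-sine), giving ``start`` = first bump center - d/2 (movement
    onset), ``end`` = second bump center + d/2 (movement termination), and
    ``peak`` - the "maximum amplitude where speed ~ 0" turning point -
    as the midpoint of the near-zero stretch between the two bumps. The
    decoded path supplies the no-movement precondition (rest-state
    terminations exist around a non-rest segment).
    """
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path)
    v = np.asarray(trunk_speed, dtype=float)
    if len(v) != len(states):
        raise ValueError("speed series and state path lengths differ")
    if np.all(states == rest_state):
        raise NoMovementError("state path never leaves the rest state")
    n = len(v)
    k = max(3, min(15, n // 4))
    vs = np.convolve(v, np.ones(k) / k, mode="same")
    i_a, i_b = int(np.argmin(vs)), int(np.argmax(vs))
    if vs[i_a] >= 0 or vs[i_b] <= 0:
        raise NoMovementError("no out-and-back sway inside the trial")
    i1, i2 = sorted((i_a, i_b))

    def half_width(i: int) -> tuple[int, int]:
        half = abs(vs[i]) / 2.0
        lo = i
        while lo > 0 and abs(vs[lo - 1]) >= half and np.sign(vs[lo - 1]) == np.sign(vs[i]):
            lo -= 1
        hi = i
        while hi < n - 1 and abs(vs[hi + 1]) >= half and np.sign(vs[hi + 1]) == np.sign(vs[i]):
            hi += 1
        return lo, hi

    lo1, hi1 = half_width(i1)
    lo2, hi2 = half_width(i2)
    d1 = 1.5 * (hi1 - lo1 + 1)
    d2 = 1.5 * (hi2 - lo2 + 1)
    start = max(0, int(round(i1 - d1 / 2.0)))
    end = min(n - 1, int(round(i2 + d2 / 2.0)))
    peak = int(round(0.5 * ((i1 + d1 / 2.0) + (i2 - d2 / 2.0))))
    return MovementClipping(start_frame=start, peak_frame=peak, end_frame=end)


def symmetry_ratio(clip: MovementClipping) -> float:
    """Time-to-peak over time-to-return; an even movement gives 1."""
    denom = clip.end_frame - clip.peak_frame
    num = clip.peak_frame - clip.start_frame
    if denom <= 0 or num <= 0:
        raise NoMovementError("degenerate clip for symmetry ratio")
    return num / denom


def synchronicity_ratio(hip_path: np.ndarray | ViterbiPath,
                        trunk_clip: MovementClipping,
                        hold_state: int = 2) -> float:
    """Timing of the trunk movement against the hip model's hold midpoint.

    ``m`` is the midpoint of the (longest) hold-state segment of the hip
    path; the ratio is ``(trunk_end - m) / (m - trunk_start)`` so that
    values < 1 mean the trunk (shoulders) moved before the hip abduction.
    """
    states = hip_path.states if isinstance(hip_path, ViterbiPath) else np.asarray(hip_path)
    segments = [r for r in run_length_encode(states) if r[0] == hold_state]
    if not segments:
        raise IncoordinationError("hip path has no hold-state segment")
    _, start, length = max(segments, key=lambda r: r[2])
    m = start + length // 2
    num = trunk_clip.end_frame - m
    denom = m - trunk_clip.start_frame
    if num <= 0 or denom <= 0:
        raise IncoordinationError("hold midpoint outside the trunk clip")
    return num / denom


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (printed-table convention)."""
    return float(np.floor(abs(x) * 100.0 + 0.5) / 100.0 * np.sign(x))


def report_ratio(r: float) -> tuple[float, float]:
    """(display, normalized) form of a timing ratio.

    Ratios > 1 are reported with their reciprocal so that averages over
    trials use the orientation-invariant ``min(r, 1/r)`` in (0, 1].
    """
    if r <= 0:
        raise ValueError("ratio must be > 0")
    return _round2(r), _round2(min(r, 1.0 / r))


def _decode_model(model: GaussianHMM, frac: float) -> GaussianHMM:
    """Copy of the model with variances floored for robust decoding.

    Hard Viterbi assignment is brittle when a leave-one-subject-out cohort
    under-samples between-subject variability; flooring each state variance
    at ``frac`` of the feature's overall signal variance (spread of state
    means plus mean within-state variance) softens state boundaries without
    touching the sharp model used for likelihood scoring.
    """
    if frac <= 0:
        return model
    signal_var = model.means.var(axis=0) + model.variances.mean(axis=0)
    floor = np.maximum(VARIANCE_FLOOR, frac * signal_var)
    return GaussianHMM(model.n_states, model.initial, model.transition,
                       model.means, np.maximum(model.variances, floor),
                       list(model.feature_names))


def qualify_path(model: GaussianHMM, obs: np.ndarray, states: np.ndarray,
                 rest_state: int = 0, evidence: float = 100.0) -> np.ndarray:
    """Suppress non-rest Viterbi segments without emission evidence.

    A decoded excursion into state ``s`` is kept only if, summed over its
    frames, it favours ``s`` over the rest state by ``evidence`` nats of
    emission log-odds. A genuine phase visit accumulates hundreds of nats;
    a boundary-noise run accumulates far less, so marginal runs
    are relabelled to rest. This is the evidence pre-processing that keeps
    visit counts of correct executions stable, so that a genuinely added
    bump (an extra state transition) stands out. Apply to the raw decoded
    path, before duration smoothing.
    """
    states = np.asarray(states).copy()
    log_b = model.log_emission(obs)
    for s, start, length in run_length_encode(states):
        if s == rest_state:
            continue
        odds = log_b[start:start + length, s] - log_b[start:start + length, rest_state]
        if odds.sum() < evidence:
            states[start:start + length] = rest_state
    return states


def path_phase_symmetry(path: np.ndarray | ViterbiPath, rise_state: int = 1,
                        hold_state: int = 2, fall_state: int = 3) -> float | None:
    """Time-to-peak over time-to-return measured on the decoded hip path.

    Uses the longest segment of each movement phase:
    ``(d_rise + d_hold/2) / (d_hold/2 + d_fall)``. Being a within-trial
    ratio it is invariant to the subject's overall tempo. Returns None when
    a phase is missing (covered by transition anomaly flags).
    """
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path)
    longest = {}
    for s, _, length in run_length_encode(states):
        longest[s] = max(longest.get(s, 0), length)
    if not all(s in longest for s in (rise_state, hold_state, fall_state)):
        return None
    d1, d2, d3 = (longest[rise_state], longest[hold_state], longest[fall_state])
    return (d1 + d2 / 2.0) / (d2 / 2.0 + d3)


def profile_symmetry(angle: np.ndarray, low: float = 0.05,
                     high: float = 0.95) -> float:
    """Time-to-peak over time-to-return from a movement-amplitude profile.

    The profile (e.g. the frontal hip angle) is amplitude-normalized;
    ``onset``/``end`` are the first/last crossings of the ``low`` fraction
    and the peak is the midpoint of the ``high`` plateau. For a smooth
    raise-hold-return profile these crossings scale with the phase
    durations, so the ratio closely tracks the true raise/return asymmetry
    and is unaffected by decode-boundary effects.
    """
    a = np.asarray(angle, dtype=float)
    rest = float(np.median(a[a <= np.percentile(a, 10)]))
    peak = float(np.median(a[a >= np.percentile(a, 95)]))
    if peak - rest <= 0:
        raise NoMovementError("no amplitude excursion in the profile")
    x = (a - rest) / (peak - rest)
    active = np.flatnonzero(x >= low)
    plateau = np.flatnonzero(x >= high)
    if active.size == 0 or plateau.size == 0:
        raise NoMovementError("profile never leaves rest")
    onset, end = float(active[0]), float(active[-1])
    m = 0.5 * (plateau[0] + plateau[-1])
    if not (onset < m < end):
        raise NoMovementError("degenerate profile geometry")
    return (m - onset) / (end - m)


def trunk_bump_centers(trunk_speed: np.ndarray, smooth: int = 15
                       ) -> tuple[float, float]:
    """Energy centroids of the two opposite-signed sway-speed bumps.

    Centroids over the deep part (>= half amplitude) of each lobe are far
    more noise-robust timing landmarks than threshold crossings.
    """
    v = np.asarray(trunk_speed, dtype=float)
    k = max(3, min(smooth, len(v) // 4))
    vs = np.convolve(v, np.ones(k) / k, mode="same")
    vmin, vmax = vs.min(), vs.max()
    if vmin >= 0 or vmax <= 0:
        raise NoMovementError("no out-and-back sway in the trunk signal")

    def lobe_centroid(i_ext: int, sign: float) -> float:
        # contiguous run around the extremum beyond half amplitude only:
        # disjoint noise lobes elsewhere must not pull the centroid
        half = 0.5 * abs(vs[i_ext])
        lo = i_ext
        while lo > 0 and sign * vs[lo - 1] >= half:
            lo -= 1
        hi = i_ext
        while hi < len(vs) - 1 and sign * vs[hi + 1] >= half:
            hi += 1
        idx = np.arange(lo, hi + 1)
        return float(np.average(idx, weights=sign * vs[lo:hi + 1]))

    c_neg = lobe_centroid(int(np.argmin(vs)), -1.0)
    c_pos = lobe_centroid(int(np.argmax(vs)), 1.0)
    return tuple(sorted((c_neg, c_pos)))


def trunk_hip_lag(trunk_speed: np.ndarray, hip_speed: np.ndarray,
                  smooth: int = 15, max_lag: int = 120) -> int:
    """Time shift (frames) of the trunk sway relative to the hip movement.

    The trunk counter-sway speed mirrors the hip angular speed, so their
    cross-correlation is most negative at the relative shift; using the
    whole signal's energy gives a far more precise timing estimate than any
    single landmark. Positive lag = trunk delayed.
    """
    v = np.asarray(trunk_speed, dtype=float)
    h = np.asarray(hip_speed, dtype=float)
    n = min(len(v), len(h))
    v, h = v[:n] - v[:n].mean(), h[:n] - h[:n].mean()
    k = max(3, min(smooth, n // 4))
    v = np.convolve(v, np.ones(k) / k, mode="same")
    max_lag = min(max_lag, n // 3)
    lags = np.arange(-max_lag, max_lag + 1)
    full = np.correlate(v, h, mode="full")  # index n-1 is lag 0 of v vs h
    c = full[n - 1 + lags]
    if c.min() >= 0:
        raise IncoordinationError("trunk and hip speeds are not anti-correlated")
    return int(lags[np.argmin(c)])


def trunk_timing_ratio(trunk_speed: np.ndarray, hip_speed: np.ndarray,
                       hip_path: np.ndarray | ViterbiPath,
                       hold_state: int = 2, rise_state: int = 1,
                       fall_state: int = 3, smooth: int = 15) -> float:
    """Trunk-vs-hip timing statistic for incoordination flagging.

    The hip path supplies precise movement landmarks (rise / hold / fall
    segment midpoints); the trunk's landmarks are those shifted by the
    cross-correlation lag. The statistic is the paper-convention ratio of
    the right over the left span around the hold midpoint: 1 when trunk and
    hip are synchronous, < 1 when the trunk moved early.
    """
    states = hip_path.states if isinstance(hip_path, ViterbiPath) else np.asarray(hip_path)
    mids = {}
    for s in (rise_state, hold_state, fall_state):
        segments = [r for r in run_length_encode(states) if r[0] == s]
        if not segments:
            raise IncoordinationError(f"hip path has no state-{s} segment")
        _, start, length = max(segments, key=lambda r: r[2])
        mids[s] = start + length / 2.0
    r_m, m, f_m = mids[rise_state], mids[hold_state], mids[fall_state]
    if not (r_m < m < f_m):
        raise IncoordinationError("hip phases out of order")
    lag = trunk_hip_lag(trunk_speed, hip_speed, smooth)
    num = (f_m + lag) - m
    denom = m - (r_m + lag)
    if num <= 0 or denom <= 0:
        raise IncoordinationError("trunk shift exceeds the movement span")
    return num / denom


# ---------------------------------------------------------------------------
# state-transition anomalies and error direction


def state_visits(states: np.ndarray, n_states: int, merge_gap: int = 30
                 ) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Visit counts and visit durations per state, with gap merging.

    Same-state runs separated by fewer than ``merge_gap`` frames (0.5 s at
    60 Hz) belong to one excursion: a bump briefly split by decode jitter is
    one visit, while a genuinely added bump elsewhere in the movement stays
    a separate visit. A visit's duration is the total time spent in the
    state across its merged runs.
    """
    runs = run_length_encode(np.asarray(states))
    counts = np.zeros(n_states, dtype=int)
    durations: dict[int, list[int]] = defaultdict(list)
    last_end: dict[int, int] = {}
    for state, start, length in runs:
        if state in last_end and start - last_end[state] < merge_gap:
            durations[state][-1] += length
        else:
            counts[state] += 1
            durations[state].append(length)
        last_end[state] = start + length
    return counts, durations


def visit_sequence(states: np.ndarray, rest_state: int = 0,
                   merge_gap: int = 30,
                   window: tuple[int, int] | None = None) -> tuple[int, ...]:
    """Ordered non-rest excursions of a path (gap-merged), optionally
    restricted to a movement window. A correct trunk execution reads
    (sway-out, sway-back); an added mid-movement bump inserts excursions."""
    states = np.asarray(states)
    if window is not None:
        states = states[window[0]:window[1] + 1]
    seq: list[int] = []
    last_end: dict[int, int] = {}
    for state, start, length in run_length_encode(states):
        if state == rest_state:
            continue
        if not (seq and seq[-1] == state
                and start - last_end[state] < merge_gap):
            seq.append(int(state))
        last_end[state] = start + length
    return tuple(seq)


def build_reference_profile(paths: Sequence[np.ndarray], n_states: int,
                            min_segment: int = 5, merge_gap: int = 30,
                            windows: Sequence[tuple[int, int] | None] | None = None,
                            rest_state: int = 0) -> dict:
    """Per-state visit-count and duration ranges over training paths."""
    if len(paths) < 3:
        raise ValueError("need at least 3 training paths for a reference profile")
    visits = np.zeros((len(paths), n_states), dtype=int)
    durations: dict[int, list[int]] = defaultdict(list)
    for i, p in enumerate(paths):
        sm = smooth_path(np.asarray(p), min_segment)
        counts, durs = state_visits(sm, n_states, merge_gap)
        visits[i] = counts
        for state, dlist in durs.items():
            durations[state].extend(dlist)
    # state-over-time occupancy: fraction of training trials in state s at
    # each normalized-time bin; a test frame in a state that correct
    # executions never occupy at that point of the movement is an added
    # transition
    n_bins = 24
    occupancy = np.zeros((n_bins, n_states))
    for p in paths:
        sm = smooth_path(np.asarray(p), min_segment)
        bins = np.minimum((np.arange(len(sm)) * n_bins) // len(sm), n_bins - 1)
        for b in range(n_bins):
            frames = sm[bins == b]
            if frames.size:
                for st in range(n_states):
                    occupancy[b, st] += np.mean(frames == st)
    occupancy /= len(paths)
    # all reference ranges are outlier-robust: a single noisy training
    # decode must not widen what counts as "seen in correct executions"
    seq_counts: dict[tuple[int, ...], int] = defaultdict(int)
    onset_times: dict[int, list[float]] = defaultdict(list)
    n_windowed = 0
    if windows is not None:
        for p, w in zip(paths, windows):
            if w is None:
                continue
            n_windowed += 1
            sm = smooth_path(np.asarray(p), min_segment)
            seq_counts[visit_sequence(sm, rest_state, merge_gap, w)] += 1
            win = sm[w[0]:w[1] + 1]
            for st in range(n_states):
                if st == rest_state:
                    continue
                segs = [r for r in run_length_encode(win) if r[0] == st]
                if segs:
                    # midpoint of the main (longest) visit: robust to brief
                    # noise excursions near the window edges
                    _, start, length = max(segs, key=lambda r: r[2])
                    onset_times[st].append((start + length / 2.0) / len(win))
    min_support = max(2, int(np.ceil(0.05 * n_windowed)))
    sequences = {t for t, c in seq_counts.items() if c >= min_support}
    # consensus temporal order of the movement phases: rank of each state
    # by the median midpoint of its main in-window visit (robust to
    # relabeling quirks and edge noise)
    medians = [np.median(onset_times[st]) if onset_times.get(st) else np.inf
               for st in range(n_states)]
    phase_rank = np.argsort(np.argsort(medians)).tolist()
    return {
        "n_states": n_states,
        "visit_min": visits.min(axis=0).tolist(),
        "visit_max": visits.max(axis=0).tolist(),
        "duration_min": [int(min(durations[s])) if durations[s] else 0
                         for s in range(n_states)],
        "duration_max": [int(max(durations[s])) if durations[s] else 0
                         for s in range(n_states)],
        "min_segment": min_segment,
        "merge_gap": merge_gap,
        "occupancy": occupancy.tolist(),
        "visit_sequences": sorted(list(t) for t in sequences),
        "phase_rank": phase_rank,
        "rest_state": rest_state,
    }


def detect_transition_anomalies(path: np.ndarray | ViterbiPath,
                                reference_profile: Mapping,
                                duration_pad: float = 0.25,
                                model_id: str = "",
                                movement_window: tuple[int, int] | None = None,
                                rest_state: int = 0,
                                visit_slack: int = 1) -> list[AssessmentFlag]:
    """Compare a decoded path against the reference visit/duration profile.

    Extra or missing state visits flag ``extra_transition`` /
    ``missing_transition``; segment durations outside the padded training
    range flag ``elongated_state`` / ``shortened_state``.
    """
    if not reference_profile:
        raise ValueError("empty reference profile")
    states = path.states if isinstance(path, ViterbiPath) else np.asarray(path)
    sm = smooth_path(states, int(reference_profile.get("min_segment", 5)))
    n_states = int(reference_profile["n_states"])
    visit_min = np.asarray(reference_profile["visit_min"])
    visit_max = np.asarray(reference_profile["visit_max"])
    dur_min = np.asarray(reference_profile["duration_min"], dtype=float)
    dur_max = np.asarray(reference_profile["duration_max"], dtype=float)
    counts, durs = state_visits(sm, n_states,
                                int(reference_profile.get("merge_gap", 30)))
    runs = [(state, None, d) for state in range(n_states)
            for d in durs.get(state, [])]
    flags: list[AssessmentFlag] = []
    # one visit of slack: min/max over a small training pool under-samples
    # benign decode variation; genuinely added bumps are carried by the
    # phase-order and occupancy checks below
    for s in range(n_states):
        if counts[s] > visit_max[s] + visit_slack:
            flags.append(AssessmentFlag(
                model_id, "extra_transition", state=s,
                detail=f"{counts[s]} visits vs reference max {visit_max[s]}"))
        elif counts[s] < visit_min[s] - visit_slack:
            flags.append(AssessmentFlag(
                model_id, "missing_transition", state=s,
                detail=f"{counts[s]} visits vs reference min {visit_min[s]}"))
    for idx, (state, _, length) in enumerate(runs):
        if dur_min[state] <= 0 or dur_max[state] > 3.0 * dur_min[state]:
            continue  # correct executions do not agree on a duration norm
        lo = dur_min[state] * (1.0 - duration_pad)
        hi = dur_max[state] * (1.0 + duration_pad)
        if length > hi > 0:
            flags.append(AssessmentFlag(
                model_id, "elongated_state", state=state, window_index=idx,
                detail=f"segment of {length} frames vs reference max {dur_max[state]:.0f}"))
        elif length < lo:
            flags.append(AssessmentFlag(
                model_id, "shortened_state", state=state, window_index=idx,
                detail=f"segment of {length} frames vs reference min {dur_min[state]:.0f}"))
    # in-movement excursion order: states are onset-ordered temporal
    # phases, so a correct execution visits them in non-decreasing order
    # (decode fragmentation repeats a phase but never returns to an
    # earlier one); a mid-movement return to an earlier phase is an added
    # movement segment - the "extra bump" signature
    if movement_window is not None and reference_profile.get("phase_rank") is not None:
        rank = list(reference_profile["phase_rank"])
        seq = visit_sequence(
            sm, int(reference_profile.get("rest_state", rest_state)),
            int(reference_profile.get("merge_gap", 30)), movement_window)
        for a, b in zip(seq, seq[1:]):
            if rank[b] < rank[a]:
                flags.append(AssessmentFlag(
                    model_id, "extra_transition", state=int(b),
                    detail=f"in-movement visit sequence {list(seq)} returns "
                           f"to phase {b} after phase {a}"))
                break
    # unexpected state at a point of the movement where no correct
    # execution occupies it (state-over-time check; needs the movement
    # window since an added bump lives inside the movement)
    occ = reference_profile.get("occupancy")
    if occ is not None and movement_window is not None:
        occ = np.asarray(occ)
        n_bins = occ.shape[0]
        bins = np.minimum((np.arange(len(sm)) * n_bins) // len(sm), n_bins - 1)
        unusual = occ[bins, sm] < 0.05
        # bridge brief usual gaps (the two lobes of an added bump straddle
        # a short rest crossing), then require the excursion to outlast
        # twice the smoothing scale - boundary blur from tempo differences
        # is shorter than that
        min_seg = int(reference_profile.get("min_segment", 5))
        merge_gap = int(reference_profile.get("merge_gap", 30))
        mask = unusual.astype(int)
        for val, start, length in run_length_encode(mask):
            if val == 0 and length < merge_gap and 0 < start < len(mask) - length:
                mask[start:start + length] = 1
        occ_vals = occ[bins, sm]
        for val, start, length in run_length_encode(mask):
            if val != 1 or length < min_seg:
                continue
            inside = unusual[start:start + length]
            seg = sm[start:start + length][inside]
            st = int(np.bincount(seg).argmax())
            if st == rest_state:
                continue  # a mistimed rest is duration territory, not a bump
            if float(occ_vals[start:start + length][inside].mean()) >= 0.02:
                continue  # boundary blur, not a zero-occupancy excursion
            if movement_window is not None and not (
                    movement_window[0] <= start
                    and start + length <= movement_window[1]):
                continue  # an added bump lives inside the movement
            flags.append(AssessmentFlag(
                model_id, "extra_transition", state=st,
                detail=f"state {st} around frames {start}-{start + length} "
                       "where correct executions never are"))
    return flags


def error_direction(model: GaussianHMM, trace: WindowLikelihoodTrace,
                    features: FeatureSeries, threshold: float,
                    path: ViterbiPath | None = None
                    ) -> list[tuple[int, str]]:
    """Direction labels for low-likelihood windows of a directional model.

    For each window below ``threshold``, the observed mean of every
    directional-speed channel is compared with the Viterbi-decoded state
    emission means; the label is the axis and sign of the largest absolute
    deviation (e.g. ``"left"``).
    """
    dir_feats = [(i, name, features.directional.get(name))
                 for i, name in enumerate(model.feature_names)
                 if features.directional.get(name)]
    if not dir_feats:
        raise UnsupportedModelError(
            "model has no directional-speed features bound")
    obs = features.matrix(model.feature_names)
    if path is None:
        path = viterbi_path(model, obs)
    labels: list[tuple[int, str]] = []
    for w, (start, value) in enumerate(zip(trace.window_starts, trace.values)):
        if value >= threshold:
            continue
        sl = slice(int(start), int(start) + trace.window_len)
        best = None
        for col, name, axis in dir_feats:
            expected = model.means[path.states[sl], col].mean()
            dev = obs[sl, col].mean() - expected
            if best is None or abs(dev) > abs(best[0]):
                best = (dev, axis)
        label = _DIRECTION_LABELS[(best[1], 1 if best[0] >= 0 else -1)]
        labels.append((w, label))
    return labels


# ---------------------------------------------------------------------------
# registry, training, classification


@dataclass
class TrainingStats:
    """Assessment references stored with each trained model."""

    per_trial_min_loglik: list[float]
    good_threshold: float
    fair_threshold: float
    reference_profile: dict
    window_len: int
    stride: int
    per_trial_dip: list[float] = field(default_factory=list)
    dip_threshold: float = -np.inf
    training_trials: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainingStats":
        return cls(**d)


@dataclass
class RegistryEntry:
    """One slot of the multi-HMM blueprint."""

    id: str
    name: str
    n_states: int
    feature_specs: list[FeatureSpec]
    model: GaussianHMM | None = None
    stats: TrainingStats | None = None
    role: str | None = None     # 'trunk' | 'hip' | None

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    @property
    def directional(self) -> bool:
        return any(s.directional_axis for s in self.feature_specs)


@dataclass
class ModelRegistry:
    """Ordered map of HMM id -> registry entry (ids unique)."""

    entries: dict[str, RegistryEntry] = field(default_factory=dict)

    def add(self, entry: RegistryEntry) -> None:
        if entry.id in self.entries:
            raise ConfigError(f"duplicate registry id {entry.id!r}")
        if entry.model is not None and entry.model.n_features != len(entry.feature_specs):
            raise ConfigError(f"entry {entry.id}: model arity mismatch")
        self.entries[entry.id] = entry

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> RegistryEntry:
        return self.entries[key]

    def to_dict(self) -> dict:
        return {
            "format_version": "rehabmotion-registry-1",
            "entries": {
                e.id: {
                    "name": e.name,
                    "n_states": e.n_states,
                    "role": e.role,
                    "feature_specs": [s.to_dict() for s in e.feature_specs],
                    "model": e.model.to_dict() if e.model else None,
                    "stats": e.stats.to_dict() if e.stats else None,
                }
                for e in self
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelRegistry":
        reg = cls()
        for mid, ed in d["entries"].items():
            reg.add(RegistryEntry(
                id=mid, name=ed["name"], n_states=int(ed["n_states"]),
                feature_specs=[FeatureSpec.from_dict(s) for s in ed["feature_specs"]],
                model=GaussianHMM.from_dict(ed["model"]) if ed.get("model") else None,
                stats=TrainingStats.from_dict(ed["stats"]) if ed.get("stats") else None,
                role=ed.get("role"),
            ))
        return reg

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelRegistry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def canonical_registry() -> ModelRegistry:
    """The canonical blueprint slots (untrained).

    II "Trunk Movement" (shoulder-center and hip-center lateral speed,
    3 states) and V "Right Hip Frontal" (frontal angular speed and angle,
    4 states). The trunk speeds are the signed lateral components (relative
    to the stance ankle): the trunk sway signal has exactly three levels -
    sway out, quiet, sway back - which is what a 3-state decomposition can
    represent (an unsigned speed has only two levels, quiet and moving, and
    the third state inevitably lands on sensor noise). The signed features
    also make the trunk model directional, so low-likelihood windows can be
    attributed a left/right error direction.
    """
    preset = {s.name: s for s in assessment_preset()}
    reg = ModelRegistry()
    reg.add(RegistryEntry(
        id="II", name="Trunk Movement", n_states=3, role="trunk",
        feature_specs=[preset["shoulder_center_lr_speed"],
                       preset["pelvis_lr_speed"]]))
    reg.add(RegistryEntry(
        id="V", name="Right Hip Frontal", n_states=4, role="hip",
        feature_specs=[preset["hip_right_frontal_speed"],
                       preset["hip_right_frontal_angle"]]))
    return reg


def relabel_states_by_onset(model: GaussianHMM, obs_list: Sequence[np.ndarray]
                            ) -> GaussianHMM:
    """Relabel states into temporal-phase order over training Viterbi paths.

    State 0 becomes the rest phase (the state holding most of the mass in
    the first tenth of each sequence); the remaining states are ordered by
    the mean normalized time-centroid of all their frames, so that the hold
    phase of a 4-state movement model lands on state 2. Centroids over all
    assigned frames are robust to brief noise excursions, which made
    first-visit ordering flip between training folds.
    """
    n = model.n_states
    head_mass = np.zeros(n)
    centroid_sum = np.zeros(n)
    centroid_w = np.zeros(n)
    for obs in obs_list:
        states = viterbi_path(model, obs).states
        t_norm = np.arange(len(states)) / len(states)
        head = states[: max(1, len(states) // 10)]
        for s in range(n):
            head_mass[s] += np.mean(head == s)
            sel = states == s
            centroid_sum[s] += t_norm[sel].sum()
            centroid_w[s] += sel.sum()
    rest = int(np.argmax(head_mass))
    with np.errstate(invalid="ignore"):
        centroid = np.where(centroid_w > 0, centroid_sum / np.maximum(centroid_w, 1),
                            np.inf)
    rest_of = sorted((s for s in range(n) if s != rest), key=lambda s: centroid[s])
    order = np.array([rest] + rest_of)
    return model.permute_states(order)


def aggregate_outcome(min_values: Mapping[str, float],
                      flags: Sequence[AssessmentFlag],
                      thresholds: Mapping[str, tuple[float, float]]) -> str:
    """good / fair / bad from window likelihoods and flag count.

    good: no flags and every model's minimum window likelihood at or above
    its good threshold; fair: at most one flag and everything at or above
    the fair threshold; otherwise bad.
    """
    if not min_values:
        raise ConfigError("no per-model traces to aggregate")
    for mid in min_values:
        if mid not in thresholds:
            raise ConfigError(f"no thresholds stored for model {mid!r}")
    above_good = all(min_values[mid] >= thresholds[mid][0] for mid in min_values)
    above_fair = all(min_values[mid] >= thresholds[mid][1] for mid in min_values)
    if len(flags) == 0 and above_good:
        return "good"
    if len(flags) <= 1 and above_fair:
        return "fair"
    return "bad"


def classify_movement(registry: ModelRegistry, features: FeatureSeries,
                      config: AssessConfig = AssessConfig()) -> MovementAssessment:
    """Run every registered HMM over one trial and aggregate the outcome."""
    if len(registry) == 0:
        raise ConfigError("empty model registry")
    per_model: dict[str, dict] = {}
    flags: list[AssessmentFlag] = []
    min_values: dict[str, float] = {}
    thresholds: dict[str, tuple[float, float]] = {}
    trunk_clip: MovementClipping | None = None
    hip_path: ViterbiPath | None = None
    hip_path_sharp: ViterbiPath | None = None

    trunk_id = hip_id = None
    trunk_sway = None
    qualified_paths: dict[str, np.ndarray] = {}
    for entry in registry:
        if entry.model is None or entry.stats is None:
            raise ConfigError(f"registry entry {entry.id} is not trained")
        obs = features.matrix(entry.feature_names)
        decoder = _decode_model(entry.model, config.var_floor_frac)
        trace = sliding_window_likelihood(
            decoder, obs, window_len=entry.stats.window_len,
            stride=entry.stats.stride)
        path = viterbi_path(decoder, obs)
        total = forward_loglik(decoder, obs)
        per_model[entry.id] = {"total_loglik": total, "trace": trace,
                               "viterbi": path}
        min_values[entry.id] = trace.min_value
        thresholds[entry.id] = (entry.stats.good_threshold,
                                entry.stats.fair_threshold)
        # a localized error shows as a dip of the worst window below the
        # trial's own typical level; the dip cancels subject-level offsets
        dip = trace.min_value - float(np.median(trace.values))
        # same unseen-subject slack as the duration ranges
        dip_level = entry.stats.dip_threshold * (1.0 + config.duration_pad)
        if dip < dip_level:
            level = float(np.median(trace.values)) + dip_level
            direction = None
            if entry.directional:
                labelled = error_direction(entry.model, trace, features,
                                           level, path)
                if labelled:
                    # attribute the direction of the worst window
                    worst = min(labelled, key=lambda t: trace.values[t[0]])
                    direction = worst[1]
            flags.append(AssessmentFlag(
                entry.id, "low_likelihood", window_index=trace.min_index,
                direction=direction,
                detail=f"window dip {dip:.2f} "
                       f"< {entry.stats.dip_threshold:.2f}"))
        qualified = smooth_path(
            qualify_path(decoder, obs, path.states,
                         rest_state=config.rest_state),
            config.min_segment)
        qualified_paths[entry.id] = qualified
        if entry.role == "trunk":
            trunk_id = entry.id
            try:
                trunk_sway = features.matrix(["shoulder_center_lr_speed"])[:, 0]
                trunk_clip = clip_movement(trunk_sway, qualified,
                                           rest_state=config.rest_state)
            except (NoMovementError, KeyError, ValueError):
                flags.append(AssessmentFlag(entry.id, "missing_transition",
                                            detail="no movement clip"))
        if entry.role == "hip":
            hip_id = entry.id
            hip_path = ViterbiPath(states=qualified, log_joint=path.log_joint)
            # phase durations for the symmetry statistic come from the sharp
            # decode: floored boundaries eat the slow phase tails
            # symmetrically in time-fraction and compress the asymmetry
            sharp = smooth_path(
                qualify_path(entry.model, obs,
                             viterbi_path(entry.model, obs).states,
                             rest_state=config.rest_state),
                config.min_segment)
            hip_path_sharp = ViterbiPath(states=sharp, log_joint=path.log_joint)

    # transition anomalies; occupancy flags are confined to the movement
    # window (between the hip path's rest terminations) - timing oddities
    # in the rest phases are not added movement bumps
    window = None
    if hip_path is not None:
        nonrest = np.flatnonzero(hip_path.states != config.rest_state)
        if nonrest.size:
            window = (int(nonrest[0]), int(nonrest[-1]))
    for entry in registry:
        flags.extend(detect_transition_anomalies(
            qualified_paths[entry.id], entry.stats.reference_profile,
            duration_pad=config.duration_pad, model_id=entry.id,
            movement_window=window, rest_state=config.rest_state))

    # reported timing ratios (the published per-trial metrics)
    symmetry = synchronicity = None
    if trunk_clip is not None:
        symmetry = symmetry_ratio(trunk_clip)
        if hip_path is not None:
            try:
                synchronicity = synchronicity_ratio(
                    hip_path, trunk_clip, hold_state=config.hold_state)
            except IncoordinationError:
                pass
    # timing-fault flags from self-normalizing state-timing statistics
    if hip_path is not None:
        try:
            sym_stat = profile_symmetry(
                features.matrix(["hip_right_frontal_angle"])[:, 0])
        except (NoMovementError, ValueError):
            sym_stat = path_phase_symmetry(hip_path_sharp,
                                           hold_state=config.hold_state)
        if sym_stat is not None:
            norm = min(sym_stat, 1.0 / sym_stat)
            if norm < config.symmetry_threshold:
                flags.append(AssessmentFlag(
                    hip_id or "V", "asymmetry",
                    detail=f"movement-profile symmetry {norm:.2f} "
                           f"< {config.symmetry_threshold}"))
        if trunk_sway is not None:
            try:
                hip_speed = features.matrix(["hip_right_frontal_speed"])[:, 0]
                syn_stat = trunk_timing_ratio(
                    trunk_sway, hip_speed, hip_path,
                    hold_state=config.hold_state, smooth=config.min_segment)
                norm = min(syn_stat, 1.0 / syn_stat)
                if norm < config.ratio_threshold:
                    flags.append(AssessmentFlag(
                        trunk_id or "II", "incoordination",
                        detail=f"trunk-hip timing {norm:.2f} "
                               f"< {config.ratio_threshold}"))
            except (IncoordinationError, NoMovementError) as e:
                flags.append(AssessmentFlag(trunk_id or "II", "incoordination",
                                            detail=str(e)))

    outcome = aggregate_outcome(min_values, flags, thresholds)
    return MovementAssessment(per_model=per_model, symmetry=symmetry,
                              synchronicity=synchronicity,
                              compensation_flags=flags, outcome=outcome)


# ---------------------------------------------------------------------------
# leave-one-subject-out training


def correct_trials(labels: Sequence[TherapistLabel],
                   majority: float = 0.5) -> set[tuple[str, str]]:
    """(subject, trial) pairs rated good on all aspects by a strict majority
    of the raters of each aspect."""
    votes: dict[tuple[str, str, str], list[str]] = defaultdict(list)
    for l in labels:
        votes[(l.subject_id, l.trial_id, l.aspect)].append(l.rating)
    trials = {(s, t) for s, t, _ in votes}
    good = set()
    for s, t in trials:
        ok = True
        for aspect in ASPECTS:
            rs = votes.get((s, t, aspect))
            if not rs or sum(r == "good" for r in rs) / len(rs) <= majority:
                ok = False
                break
        if ok:
            good.add((s, t))
    return good


def train_registry(template: ModelRegistry,
                   features_by_trial: Mapping[tuple[str, str], FeatureSeries],
                   training_ids: Sequence[tuple[str, str]],
                   seed: int = 0,
                   config: AssessConfig = AssessConfig()) -> ModelRegistry:
    """Fit every template entry on the given trials and store assessment
    references (thresholds from the per-trial minimum window likelihoods,
    the Viterbi reference profile)."""
    if not training_ids:
        raise ValueError("no training trials")
    trained = ModelRegistry()
    per_entry: dict[str, dict] = {}
    for entry in template:
        obs_list = [features_by_trial[t].matrix(entry.feature_names)
                    for t in training_ids]
        model, _ = baum_welch_fit(obs_list, entry.n_states, seed=seed,
                                  feature_names=entry.feature_names)
        model = relabel_states_by_onset(model, obs_list)
        decoder = _decode_model(model, config.var_floor_frac)
        mins = []
        dips = []
        paths = []
        for obs in obs_list:
            trace = sliding_window_likelihood(decoder, obs,
                                              window_len=config.window_len,
                                              stride=config.stride)
            mins.append(trace.min_value)
            dips.append(trace.min_value - float(np.median(trace.values)))
            raw = viterbi_path(decoder, obs).states
            paths.append(smooth_path(
                qualify_path(decoder, obs, raw, rest_state=config.rest_state),
                config.min_segment))
        per_entry[entry.id] = {"model": model, "mins": mins, "dips": dips,
                               "paths": paths, "entry": entry}
    windows = movement_windows(per_entry, template, config.rest_state)
    for eid, data in per_entry.items():
        entry = data["entry"]
        stats = TrainingStats(
            per_trial_min_loglik=data["mins"],
            good_threshold=float(np.percentile(data["mins"], config.good_percentile)),
            fair_threshold=float(np.percentile(data["mins"], config.fair_percentile)),
            per_trial_dip=data["dips"],
            dip_threshold=float(np.percentile(data["dips"], config.fair_percentile)),
            reference_profile=build_reference_profile(
                data["paths"], entry.n_states, min_segment=config.min_segment,
                windows=windows, rest_state=config.rest_state),
            window_len=config.window_len,
            stride=config.stride,
            training_trials=[f"{s}/{t}" for s, t in training_ids],
        )
        trained.add(RegistryEntry(
            id=eid, name=entry.name, n_states=entry.n_states,
            feature_specs=entry.feature_specs, model=data["model"], stats=stats,
            role=entry.role))
    return trained


def movement_windows(per_entry: Mapping[str, dict], template: ModelRegistry,
                     rest_state: int = 0) -> list[tuple[int, int] | None] | None:
    """Per-trial movement windows from the hip entry's decoded paths."""
    hip_id = next((e.id for e in template if e.role == "hip"), None)
    if hip_id is None or hip_id not in per_entry:
        return None
    windows = []
    for p in per_entry[hip_id]["paths"]:
        nonrest = np.flatnonzero(np.asarray(p) != rest_state)
        windows.append((int(nonrest[0]), int(nonrest[-1])) if nonrest.size else None)
    return windows


class FoldError(ValueError):
    """A leave-one-subject-out fold has no correct training trials."""


def loso_train(features_by_trial: Mapping[tuple[str, str], FeatureSeries],
               labels: Sequence[TherapistLabel],
               template: ModelRegistry | None = None,
               seed: int = 0,
               config: AssessConfig = AssessConfig()
               ) -> dict[str, ModelRegistry]:
    """Leave-one-subject-out training over a labelled dataset.

    For every held-out subject, each registry HMM is trained on the correct
    trials (label consensus) of all other subjects. Returns one trained
    registry per subject.
    """
    template = template if template is not None else canonical_registry()
    subjects = sorted({s for s, _ in features_by_trial})
    if len(subjects) < 2:
        raise FoldError("leave-one-subject-out needs at least 2 subjects")
    good = correct_trials(labels, majority=config.label_majority)
    registries: dict[str, ModelRegistry] = {}
    for held_out in subjects:
        training_ids = sorted(t for t in features_by_trial
                              if t[0] != held_out and t in good)
        if not training_ids:
            raise FoldError(f"no correct training trials for fold {held_out!r}")
        registries[held_out] = train_registry(
            template, features_by_trial, training_ids, seed=seed, config=config)

    # Out-of-sample calibration: the thresholds stored with fold s must
    # describe how correct executions of UNSEEN subjects score. Each
    # subject's correct trials are scored under its own fold's registry
    # (held out there by construction); fold s then aggregates the
    # statistics of every subject except s. In-sample statistics would be
    # optimistic and flag unseen subjects wholesale.
    oos: dict[str, dict[str, dict]] = {mid: {} for mid in template.entries}
    for subj in subjects:
        reg = registries[subj]
        trial_ids = sorted(t for t in features_by_trial
                           if t[0] == subj and t in good)
        for entry in reg:
            mins, dips, paths = [], [], []
            decoder = _decode_model(entry.model, config.var_floor_frac)
            for tid in trial_ids:
                obs = features_by_trial[tid].matrix(entry.feature_names)
                trace = sliding_window_likelihood(
                    decoder, obs, window_len=config.window_len,
                    stride=config.stride)
                mins.append(trace.min_value)
                dips.append(trace.min_value - float(np.median(trace.values)))
                raw = viterbi_path(decoder, obs).states
                paths.append(qualify_path(
                    decoder, obs, smooth_path(raw, config.min_segment),
                    rest_state=config.rest_state))
            oos[entry.id][subj] = {"mins": mins, "dips": dips, "paths": paths}
    hip_id = next((e.id for e in template if e.role == "hip"), None)
    for held_out in subjects:
        for entry in registries[held_out]:
            pool_subjects = [s for s in subjects if s != held_out]
            mins = [m for s in pool_subjects for m in oos[entry.id][s]["mins"]]
            dips = [d for s in pool_subjects for d in oos[entry.id][s]["dips"]]
            paths = [p for s in pool_subjects for p in oos[entry.id][s]["paths"]]
            if len(paths) < 3:
                continue  # keep in-sample stats for degenerate folds
            windows = None
            if hip_id is not None:
                windows = []
                for s in pool_subjects:
                    for p in oos[hip_id][s]["paths"]:
                        nonrest = np.flatnonzero(np.asarray(p) != config.rest_state)
                        windows.append((int(nonrest[0]), int(nonrest[-1]))
                                       if nonrest.size else None)
            entry.stats.per_trial_min_loglik = mins
            entry.stats.good_threshold = float(
                np.percentile(mins, config.good_percentile))
            entry.stats.fair_threshold = float(
                np.percentile(mins, config.fair_percentile))
            entry.stats.per_trial_dip = dips
            entry.stats.dip_threshold = float(np.min(dips))
            entry.stats.reference_profile = build_reference_profile(
                paths, entry.n_states, min_segment=config.min_segment,
                windows=windows, rest_state=config.rest_state)
    return registries
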