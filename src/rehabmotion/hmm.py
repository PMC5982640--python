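"""Gaussian-emission Hidden Markov Models: likelihood, decoding, training,
sampling and state-count selection.

The model is the classic factorized joint probability over a hidden state
sequence ``h_1..h_n`` and observations ``o_1..o_n``::

    p(o, h) = pi(h_1) e_{h_1}(o_1) * prod_i T(h_{i-1}, h_i) e_{h_i}(o_i)

with initial distribution ``pi``, row-stochastic transition matrix ``T`` and
per-state diagonal-covariance Gaussian emissions ``e_l``. Movement phases
(rest, rise, hold, return) map naturally onto states, so initialization
slices each training sequence into temporal quantiles, concentrates ``pi``
on state 0 and starts from sticky transitions; the transition topology
itself stays ergodic.

All recursions run in scaled/log space (no underflow up to 1e5 frames) in
numba-compiled kernels; Viterbi ties break toward the lower state index, and
training is deterministic given its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "GaussianHMM",
    "ViterbiPath",
    "FitReport",
    "VARIANCE_FLOOR",
    "forward_loglik",
    "viterbi_path",
    "baum_welch_fit",
    "bic_scan",
    "n_free_parameters",
    "sample_sequence",
    "save_model",
    "load_model",
]

VARIANCE_FLOOR = 1e-6
_FORMAT_VERSION = "rehabmotion-hmm-1"


@dataclass
class GaussianHMM:
    """pi, T and per-state diagonal Gaussian emissions over named features."""

    n_states: int
    initial: np.ndarray        # (n,)
    transition: np.ndarray     # (n, n), rows sum to 1
    means: np.ndarray          # (n, d)
    variances: np.ndarray      # (n, d), diagonal covariances
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.n_features)]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        n = self.n_states
        if n < 1:
            raise ValueError("n_states must be >= 1")
        if self.initial.shape != (n,) or self.transition.shape != (n, n):
            raise ValueError("initial/transition shape mismatch")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution does not sum to 1")
        if np.any((self.initial < -1e-12) | (self.initial > 1 + 1e-12)):
            raise ValueError("initial probabilities outside [0, 1]")
        rows = self.transition.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("transition rows do not sum to 1")
        if np.any((self.transition < -1e-12) | (self.transition > 1 + 1e-12)):
            raise ValueError("transition probabilities outside [0, 1]")
        if np.any(self.variances < VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValueError("variance below floor")
        if self.means.shape != self.variances.shape:
            raise ValueError("means/variances shape mismatch")

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """Per-frame, per-state emission log-densities, shape (T, n)."""
        obs = _as_obs(obs, self.n_features)
        # (T, 1, d) - (n, d) -> (T, n, d)
        z2 = (obs[:, None, :] - self.means[None, :, :]) ** 2 / self.variances[None, :, :]
        const = np.log(2.0 * np.pi * self.variances).sum(axis=1)  # (n,)
        return -0.5 * (z2.sum(axis=2) + const[None, :])

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "n_states": int(self.n_states),
            "feature_names": list(self.feature_names),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        if d.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')!r}")
        return cls(
            n_states=int(d["n_states"]),
            initial=np.array(d["initial"], dtype=float),
            transition=np.array(d["transition"], dtype=float),
            means=np.array(d["means"], dtype=float),
            variances=np.array(d["variances"], dtype=float),
            feature_names=list(d["feature_names"]),
        )

    def permute_states(self, order: Sequence[int]) -> "GaussianHMM":
        """Relabel states so that new state ``i`` is old state ``order[i]``."""
        order = np.asarray(order, dtype=int)
        return GaussianHMM(
            n_states=self.n_states,
            initial=self.initial[order],
            transition=self.transition[np.ix_(order, order)],
            means=self.means[order],
            variances=self.variances[order],
            feature_names=list(self.feature_names),
        )


@dataclass
class ViterbiPath:
    """Most probable state sequence and its factorized log-probability."""

    states: np.ndarray
    log_joint: float

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class FitReport:
    """EM diagnostics; the log-likelihood trace is non-decreasing."""

    log_likelihood_trace: list[float]
    n_iterations: int
    converged: bool
    seed: int
    collapsed_states: list[int] = field(default_factory=list)


def _as_obs(obs, n_features: int | None = None) -> np.ndarray:
    """Coerce a FeatureSeries / array into a (T, d) observation matrix."""
    if hasattr(obs, "matrix"):  # FeatureSeries
        obs = obs.matrix()
    obs = np.asarray(obs, dtype=float)
    if obs.ndim == 1:
        obs = obs[:, None]
    if obs.ndim != 2:
        raise ValueError("observations must be (T, d)")
    if np.isnan(obs).any():
        raise ValueError("observations contain NaN (slice from valid_from)")
    if n_features is not None and obs.shape[1] != n_features:
        raise ValueError(
            f"observation arity {obs.shape[1]} != model arity {n_features}"
        )
    return obs


# ---------------------------------------------------------------------------
# numba kernels (scaled forward-backward, log-space Viterbi)


@njit(cache=True)
def _forward_kernel(pi, a, log_b):
    t_len, n = log_b.shape
    loglik = 0.0
    alpha = np.empty(n)
    nxt = np.empty(n)
    m0 = log_b[0].max()
    for l in range(n):
        alpha[l] = pi[l] * np.exp(log_b[0, l] - m0)
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf, alpha
    alpha /= c
    loglik += np.log(c) + m0
    for t in range(1, t_len):
        mt = log_b[t].max()
        for k in range(n):
            s = 0.0
            for j in range(n):
                s += alpha[j] * a[j, k]
            nxt[k] = s * np.exp(log_b[t, k] - mt)
        c = nxt.sum()
        if c <= 0.0:
            return -np.inf, alpha
        for k in range(n):
            alpha[k] = nxt[k] / c
        loglik += np.log(c) + mt
    return loglik, alpha


@njit(cache=True)
def _forward_backward_kernel(pi, a, log_b):
    """Returns (loglik, gamma (T,n), xi_sum (n,n))."""
    t_len, n = log_b.shape
    bs = np.empty((t_len, n))
    for t in range(t_len):
        mt = log_b[t].max()
        for l in range(n):
            bs[t, l] = np.exp(log_b[t, l] - mt)
    # forward with per-step normalization
    alpha = np.empty((t_len, n))
    cs = np.empty(t_len)
    loglik = 0.0
    for l in range(n):
        alpha[0, l] = pi[l] * bs[0, l]
    cs[0] = alpha[0].sum()
    alpha[0] /= cs[0]
    for t in range(1, t_len):
        for k in range(n):
            s = 0.0
            for j in range(n):
                s += alpha[t - 1, j] * a[j, k]
            alpha[t, k] = s * bs[t, k]
        cs[t] = alpha[t].sum()
        alpha[t] /= cs[t]
    for t in range(t_len):
        mt = log_b[t].max()
        loglik += np.log(cs[t]) + mt
    # backward, same scaling
    beta = np.empty((t_len, n))
    for l in range(n):
        beta[t_len - 1, l] = 1.0
    for t in range(t_len - 2, -1, -1):
        for j in range(n):
            s = 0.0
            for k in range(n):
                s += a[j, k] * bs[t + 1, k] * beta[t + 1, k]
            beta[t, j] = s / cs[t + 1]
    gamma = np.empty((t_len, n))
    for t in range(t_len):
        tot = 0.0
        for l in range(n):
            gamma[t, l] = alpha[t, l] * beta[t, l]
            tot += gamma[t, l]
        for l in range(n):
            gamma[t, l] /= tot
    xi_sum = np.zeros((n, n))
    for t in range(t_len - 1):
        for j in range(n):
            for k in range(n):
                xi_sum[j, k] += (alpha[t, j] * a[j, k] * bs[t + 1, k]
                                 * beta[t + 1, k] / cs[t + 1])
    return loglik, gamma, xi_sum


@njit(cache=True)
def _viterbi_kernel(log_pi, log_a, log_b):
    t_len, n = log_b.shape
    delta = np.empty((t_len, n))
    psi = np.zeros((t_len, n), dtype=np.int64)
    for l in range(n):
        delta[0, l] = log_pi[l] + log_b[0, l]
    for t in range(1, t_len):
        for k in range(n):
            best = -np.inf
            arg = 0
            for j in range(n):
                v = delta[t - 1, j] + log_a[j, k]
                if v > best:  # strict: ties keep the lower state index
                    best = v
                    arg = j
            delta[t, k] = best + log_b[t, k]
            psi[t, k] = arg
    states = np.empty(t_len, dtype=np.int64)
    best = -np.inf
    arg = 0
    for l in range(n):
        if delta[t_len - 1, l] > best:
            best = delta[t_len - 1, l]
            arg = l
    states[t_len - 1] = arg
    for t in range(t_len - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states, best


# ---------------------------------------------------------------------------
# public operations


def forward_loglik(model: GaussianHMM, obs) -> float:
    """Log-probability of the observations, marginalized over state paths."""
    model.validate()
    obs = _as_obs(obs, model.n_features)
    log_b = model.log_emission(obs)
    loglik, _ = _forward_kernel(model.initial, model.transition, log_b)
    return float(loglik)


def viterbi_path(model: GaussianHMM, obs) -> ViterbiPath:
    """Most probable state path; ties break toward the lower state index."""
    model.validate()
    obs = _as_obs(obs, model.n_features)
    log_b = model.log_emission(obs)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.initial)
        log_a = np.log(model.transition)
    states, log_joint = _viterbi_kernel(log_pi, log_a, log_b)
    return ViterbiPath(states=states, log_joint=float(log_joint))


def _quantile_init(observations: list[np.ndarray], n_states: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Initial emission parameters from temporal quantile slices.

    State ``l`` starts at the pooled mean/variance of the ``l``-th temporal
    segment of every sequence, reflecting the phase semantics of the states.
    """
    d = observations[0].shape[1]
    means = np.zeros((n_states, d))
    variances = np.zeros((n_states, d))
    for l in range(n_states):
        chunks = []
        for obs in observations:
            bounds = np.linspace(0, len(obs), n_states + 1).astype(int)
            seg = obs[bounds[l]:max(bounds[l + 1], bounds[l] + 1)]
            chunks.append(seg)
        pooled = np.concatenate(chunks, axis=0)
        means[l] = pooled.mean(axis=0)
        variances[l] = np.maximum(pooled.var(axis=0), VARIANCE_FLOOR)
    return means, variances


def baum_welch_fit(observations, n_states: int, max_iter: int = 200,
                   tol: float = 1e-4, seed: int = 0,
                   feature_names: Sequence[str] | None = None,
                   var_floor_frac: float = 0.0
                   ) -> tuple[GaussianHMM, FitReport]:
    """Fit a Gaussian HMM by multi-sequence Baum-Welch EM.

    ``observations`` is one (T, d) array / FeatureSeries or a list of them.
    Sufficient statistics are summed over sequences; iteration stops when
    the total log-likelihood gain falls below ``tol`` or at ``max_iter``.
    Deterministic given ``seed`` (randomness is only used to re-seed a
    collapsed state at a random data point).

    ``var_floor_frac`` optionally floors each state variance at that
    fraction of the feature's global variance (relative variance flooring,
    standard practice against over-tight emissions when training cohorts
    under-sample between-subject variability).
    """
    if observations is None:
        raise ValueError("empty observation set")
    if hasattr(observations, "matrix") or isinstance(observations, np.ndarray):
        observations = [observations]
    obs_list = [_as_obs(o) for o in observations]
    if not obs_list:
        raise ValueError("empty observation set")
    d = obs_list[0].shape[1]
    for o in obs_list:
        if o.shape[1] != d:
            raise ValueError("sequences have inconsistent arity")
    total_frames = sum(len(o) for o in obs_list)
    if total_frames < 10 * n_states:
        raise ValueError(
            f"{total_frames} frames is too few for {n_states} states "
            f"(need >= {10 * n_states})"
        )
    rng = np.random.default_rng(seed)
    all_data = np.concatenate(obs_list, axis=0)
    global_var = np.maximum(all_data.var(axis=0), VARIANCE_FLOOR)
    floor = np.maximum(VARIANCE_FLOOR, var_floor_frac * global_var)

    means, variances = _quantile_init(obs_list, n_states)
    variances = np.maximum(variances, floor)
    if n_states == 1:
        initial = np.ones(1)
        transition = np.ones((1, 1))
    else:
        initial = np.full(n_states, 0.1 / (n_states - 1))
        initial[0] = 0.9
        transition = np.full((n_states, n_states), 0.1 / (n_states - 1))
        np.fill_diagonal(transition, 0.9)

    model = GaussianHMM(n_states, initial, transition, means, variances,
                        list(feature_names) if feature_names else [])
    trace: list[float] = []
    collapsed: list[int] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        loglik = 0.0
        g0 = np.zeros(n_states)
        g_sum = np.zeros(n_states)
        g_obs = np.zeros((n_states, d))
        g_obs2 = np.zeros((n_states, d))
        xi_tot = np.zeros((n_states, n_states))
        for obs in obs_list:
            log_b = model.log_emission(obs)
            ll, gamma, xi = _forward_backward_kernel(
                model.initial, model.transition, log_b)
            loglik += ll
            g0 += gamma[0]
            g_sum += gamma.sum(axis=0)
            g_obs += gamma.T @ obs
            g_obs2 += gamma.T @ (obs ** 2)
            xi_tot += xi
        # variance flooring / collapse re-seeding make the M-step a
        # constrained maximizer, so a marginal decrease can occur in
        # degenerate fits: treat it as convergence and keep the trace
        # non-decreasing rather than record the dip
        if trace and float(loglik) - trace[-1] < tol:
            converged = True
            if float(loglik) > trace[-1]:
                trace.append(float(loglik))
            break
        trace.append(float(loglik))
        # M step
        new_pi = g0 / g0.sum()
        row = xi_tot.sum(axis=1, keepdims=True)
        new_a = np.where(row > 0, xi_tot / np.maximum(row, 1e-300),
                         model.transition)
        new_a /= new_a.sum(axis=1, keepdims=True)
        new_means = g_obs / np.maximum(g_sum[:, None], 1e-300)
        new_var = g_obs2 / np.maximum(g_sum[:, None], 1e-300) - new_means ** 2
        new_var = np.maximum(new_var, floor)
        for l in range(n_states):
            if g_sum[l] < 1.0:  # state collapse: re-seed at a random point
                idx = int(rng.integers(0, len(all_data)))
                new_means[l] = all_data[idx]
                new_var[l] = global_var
                collapsed.append(l)
        model = GaussianHMM(n_states, new_pi, new_a, new_means, new_var,
                            model.feature_names)
        model.validate()
    report = FitReport(log_likelihood_trace=trace, n_iterations=it,
                       converged=converged, seed=seed,
                       collapsed_states=collapsed)
    return model, report


def n_free_parameters(n_states: int, n_features: int) -> int:
    """Free parameters of a diagonal-Gaussian HMM:
    (n-1) initial + n(n-1) transition + 2nd emission."""
    return (n_states - 1) + n_states * (n_states - 1) + 2 * n_states * n_features


def bic_scan(observations, state_range: Iterable[int] = range(2, 11),
             n_folds: int = 3, seed: int = 0, max_iter: int = 200,
             tol: float = 1e-4) -> tuple[pd.DataFrame, int]:
    """Cross-validated BIC over candidate state counts.

    For each state count, fits on the training folds and scores
    ``BIC = k ln(N) - 2 lnL`` on the held-out fold (``N`` = held-out frame
    count), averaged over folds. Returns the score table and the argmin.
    """
    obs_list = [_as_obs(o) for o in (observations if isinstance(observations, (list, tuple)) else [observations])]
    state_range = list(state_range)
    if min(state_range) < 2 or max(state_range) > 10:
        warnings.warn("state counts outside [2, 10]; a HMM has at least 2 "
                      "states and the trainer exposes 2-10", stacklevel=2)
    if n_folds > len(obs_list):
        raise ValueError(f"{len(obs_list)} sequences cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs_list))
    folds = np.array_split(order, n_folds)
    d = obs_list[0].shape[1]
    rows = []
    for n in state_range:
        k = n_free_parameters(n, d)
        scores = []
        for f, held in enumerate(folds):
            held_set = set(held.tolist())
            if n_folds == 1:
                train = obs_list
            else:
                train = [o for i, o in enumerate(obs_list) if i not in held_set]
            test = [obs_list[i] for i in held]
            model, _ = baum_welch_fit(train, n, max_iter=max_iter, tol=tol,
                                      seed=seed + f)
            n_held = sum(len(o) for o in test)
            lnl = sum(forward_loglik(model, o) for o in test)
            scores.append(k * np.log(n_held) - 2.0 * lnl)
        rows.append((n, float(np.mean(scores))))
    table = pd.DataFrame(rows, columns=["n_states", "bic"])
    best = int(table.loc[table["bic"].idxmin(), "n_states"])
    return table, best


def sample_sequence(model: GaussianHMM, length: int, seed: int = 0) -> np.ndarray:
    """Draw one observation sequence from the generative process."""
    if length < 1:
        raise ValueError("length must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(1, length):
        states[t] = rng.choice(model.n_states, p=model.transition[states[t - 1]])
    obs = model.means[states] + rng.standard_normal((length, model.n_features)) \
        * np.sqrt(model.variances[states])
    return obs


def sample_sequence_with_states(model: GaussianHMM, length: int, seed: int = 0
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`sample_sequence` but also returns the hidden states
    (identical draws for the same seed)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(1, length):
        states[t] = rng.choice(model.n_states, p=model.transition[states[t - 1]])
    obs = model.means[states] + rng.standard_normal((length, model.n_features)) \
        * np.sqrt(model.variances[states])
    return obs, states


def save_model(model: GaussianHMM, path: str | Path) -> Path:
    """Serialize to JSON; the round trip is bit-exact (repr-precision floats)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    return path


def load_model(path: str | Path) -> GaussianHMM:
    with open(path) as fh:
        return GaussianHMM.from_dict(json.load(fh))
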