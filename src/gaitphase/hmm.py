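"""Continuous-emission hidden Markov machinery.

The gait-phase classifiers use a cyclic left-right HMM with univariate
Gaussian-mixture emissions: state ``i`` may stay (probability
``1 - 1/d_i``, with ``d_i`` its expected duration in samples) or advance to
state ``i+1`` (wrapping to the first state, since a treadmill trial spans
many strides). Training is Baum-Welch EM; decoding is exact Viterbi or a
fixed-lag online variant. All recursions run in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

LOG_FLOOR = -700.0  # ~ log(1e-304); keeps exp() away from denormals
_ATOL = 1e-10


@dataclass
class HmmParams:
    """Parameter set (A, pi, w, mu, sigma) of one classifier.

    ``A`` is an ``n x n`` row-stochastic transition matrix whose structural
    zeros (entries outside the allowed left-right transitions) stay exactly
    zero through training; ``w``, ``mu``, ``sigma`` have shape
    ``(n, n_mix)`` with mixture weights summing to one per state. ``mu`` and
    ``sigma`` are in deg/s.
    """

    A: np.ndarray
    pi: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        self.validate()

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_mix(self) -> int:
        return self.w.shape[1]

    def validate(self) -> None:
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=_ATOL):
            raise ValueError("rows of A must sum to 1")
        if (self.A < 0).any():
            raise ValueError("A entries must be nonnegative")
        if self.pi.shape != (n,) or not np.isclose(self.pi.sum(), 1.0, atol=_ATOL):
            raise ValueError("pi must be a length-n distribution")
        for name, arr in (("w", self.w), ("mu", self.mu), ("sigma", self.sigma)):
            if arr.shape != self.w.shape:
                raise ValueError(f"{name} must have shape (n_states, n_mix)")
        if self.w.shape[0] != n:
            raise ValueError("w must have n_states rows")
        if not np.allclose(self.w.sum(axis=1), 1.0, atol=_ATOL):
            raise ValueError("rows of w must sum to 1")
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")

    def copy(self) -> "HmmParams":
        return HmmParams(self.A.copy(), self.pi.copy(), self.w.copy(),
                         self.mu.copy(), self.sigma.copy())

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "A": self.A.tolist(),
            "pi": self.pi.tolist(),
            "w": self.w.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        return cls(np.array(d["A"]), np.array(d["pi"]), np.array(d["w"]),
                   np.array(d["mu"]), np.array(d["sigma"]))

    def save(self, path: str | Path, **metadata) -> None:
        payload = self.to_dict()
        payload["metadata"] = metadata
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> tuple["HmmParams", dict]:
        d = json.loads(Path(path).read_text())
        return cls.from_dict(d), d.get("metadata", {})


@dataclass
class DecodeResult:
    """Most likely state path plus per-sample state posteriors."""

    states: np.ndarray  # (T,) int
    gamma: np.ndarray  # (T, n) posteriors, rows sum to 1
    loglik: float  # sequence log-likelihood (forward recursion)


# ---------------------------------------------------------------------------
# Construction helpers

def build_left_right_A(
    n_states: int,
    expected_durations_samples: Sequence[float],
    cyclic: bool = True,
) -> np.ndarray:
    """Left-right transition matrix from expected state durations.

    ``a_ii = 1 - 1/d_i`` and ``a_{i,i+1} = 1/d_i`` (the last state wraps to
    the first when ``cyclic``); all other entries are exactly zero.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    d = np.asarray(expected_durations_samples, dtype=float)
    if d.shape != (n_states,):
        raise ValueError("need one expected duration per state")
    if (d < 1).any():
        raise ValueError("expected durations must be >= 1 sample")
    A = np.zeros((n_states, n_states))
    for i in range(n_states):
        if n_states == 1:
            A[i, i] = 1.0
            continue
        stay = 1.0 - 1.0 / d[i]
        if i + 1 < n_states:
            A[i, i] = stay
            A[i, i + 1] = 1.0 - stay
        elif cyclic:
            A[i, i] = stay
            A[i, 0] = 1.0 - stay
        else:
            A[i, i] = 1.0
    return A


def uniform_pi(n_states: int) -> np.ndarray:
    """Uniform initial-state distribution (initial phase unknown)."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    return np.full(n_states, 1.0 / n_states)


# ---------------------------------------------------------------------------
# Emission densities

def log_emission_matrix(params: HmmParams, obs: np.ndarray) -> np.ndarray:
    """Per-sample per-state log emission density, shape (T, n)."""
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1:
        raise ValueError("observations must be one-dimensional")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations contain NaN or infinite values")
    # (T, n, m)
    z = norm.logpdf(obs[:, None, None], loc=params.mu[None], scale=params.sigma[None])
    with np.errstate(divide="ignore"):
        logw = np.where(params.w > 0, np.log(np.maximum(params.w, 1e-300)), -np.inf)
    logB = logsumexp(z + logw[None], axis=2)
    return np.maximum(logB, LOG_FLOOR)


def _log_mask(M: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(M > 0, np.log(np.maximum(M, 1e-300)), -np.inf)


# ---------------------------------------------------------------------------
# Forward-backward (scaled linear-space recursions)

def _fb_scaled(pi: np.ndarray, A: np.ndarray, logB: np.ndarray):
    """Scaled forward-backward given per-sample log emission densities.

    Emissions are rescaled per time step (max-shift) before exponentiation;
    the per-step normalizers recover the exact log-likelihood.
    """
    T, n = logB.shape
    shift = logB.max(axis=1)
    Bh = np.exp(logB - shift[:, None])  # in (0, 1], max of each row = 1

    alpha = np.empty((T, n))
    c = np.empty(T)
    a = pi * Bh[0]
    c[0] = a.sum()
    if c[0] <= 0:
        a = np.full(n, 1.0 / n)
        c[0] = 1e-300
    alpha[0] = a / c[0] if c[0] > 0 else a
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bh[t]
        s = a.sum()
        if s <= 0:
            a = np.full(n, 1.0 / n)
            s = 1e-300
        c[t] = s
        alpha[t] = a / s

    beta = np.empty((T, n))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        b = A @ (Bh[t + 1] * beta[t + 1])
        beta[t] = b / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(np.maximum(c, 1e-300)).sum() + shift.sum())
    return alpha, beta, Bh, c, gamma, loglik


def forward_backward(params: HmmParams, obs: np.ndarray,
                     logB: Optional[np.ndarray] = None):
    """State posteriors and sequence log-likelihood.

    Returns ``(gamma, loglik)``: per-sample state posteriors (rows summing
    to one) and the exact sequence log-likelihood.
    """
    if logB is None:
        logB = log_emission_matrix(params, obs)
    _, _, _, _, gamma, loglik = _fb_scaled(params.pi, params.A, logB)
    return gamma, loglik


# ---------------------------------------------------------------------------
# Baum-Welch

def baum_welch(
    init: HmmParams,
    sequences: Sequence[np.ndarray] | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    var_floor: Optional[float] = None,
    update_pi: bool = True,
) -> tuple[HmmParams, list[float]]:
    """EM re-estimation of a Gaussian-mixture HMM on one or more sequences.

    The structural zeros of ``A`` are preserved exactly (a zero transition
    accumulates zero expected counts). ``var_floor`` is a lower bound on the
    emission standard deviations, defaulting to ``1e-2`` of the pooled
    training-signal standard deviation; it guards degenerate states that
    capture near-constant signal stretches.

    Returns the trained parameters and the per-iteration total
    log-likelihood trace (non-decreasing up to numerical slack).
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    if not sequences:
        raise ValueError("empty sequence set")
    n = init.n_states
    for s in sequences:
        if not np.all(np.isfinite(s)):
            raise ValueError("observations contain NaN or infinite values")
        if s.size < n:
            raise ValueError("every sequence must be at least n_states long")
    pooled = np.concatenate(sequences)
    if var_floor is None:
        var_floor = max(1e-2 * float(pooled.std()), 1e-8)

    params = init.copy()
    m = params.n_mix
    trace: list[float] = []

    for _ in range(max_iter):
        A_num = np.zeros((n, n))
        pi_num = np.zeros(n)
        g_sum = np.zeros((n, m))
        gx_sum = np.zeros((n, m))
        gxx_sum = np.zeros((n, m))
        total_ll = 0.0

        for obs in sequences:
            logB = log_emission_matrix(params, obs)
            alpha, beta, Bh, c, gamma, ll = _fb_scaled(params.pi, params.A, logB)
            total_ll += ll
            # expected transition counts, only where A > 0:
            # xi_t = alpha_t (x) (Bhat_{t+1} * beta_{t+1} / c_{t+1}) .* A
            if obs.size > 1:
                right = Bh[1:] * beta[1:] / c[1:, None]
                A_num += params.A * (alpha[:-1].T @ right)
            pi_num += gamma[0]
            # per-mixture responsibilities
            z = norm.logpdf(obs[:, None, None], loc=params.mu[None],
                            scale=params.sigma[None]) + _log_mask(params.w)[None]
            z -= logsumexp(z, axis=2, keepdims=True)
            comp = np.exp(z) * gamma[:, :, None]  # (T, n, m)
            g_sum += comp.sum(axis=0)
            gx_sum += (comp * obs[:, None, None]).sum(axis=0)
            gxx_sum += (comp * (obs[:, None, None] ** 2)).sum(axis=0)

        trace.append(total_ll)

        # M-step
        row = A_num.sum(axis=1, keepdims=True)
        A_new = np.divide(A_num, row, out=params.A.copy(), where=row > 0)
        A_new[(params.A == 0)] = 0.0
        rs = A_new.sum(axis=1, keepdims=True)
        A_new = np.divide(A_new, rs, out=A_new, where=rs > 0)
        params.A = A_new
        if update_pi:
            params.pi = pi_num / pi_num.sum()
        denom = np.maximum(g_sum, 1e-300)
        params.mu = gx_sum / denom
        var = gxx_sum / denom - params.mu**2
        params.sigma = np.sqrt(np.maximum(var, var_floor**2))
        state_tot = denom.sum(axis=1, keepdims=True)
        params.w = denom / state_tot
        params.validate()

        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                break

    return params, trace


# ---------------------------------------------------------------------------
# Decoding

def _viterbi_trellis(logpi: np.ndarray, logA: np.ndarray, logB: np.ndarray):
    T, n = logB.shape
    delta = np.empty((T, n))
    psi = np.zeros((T, n), dtype=np.int64)
    delta[0] = logpi + logB[0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + logA
        psi[t] = np.argmax(scores, axis=0)
        delta[t] = scores[psi[t], np.arange(n)] + logB[t]
    return delta, psi


def _backtrack(psi: np.ndarray, last: int, t_end: int, t_start: int) -> np.ndarray:
    """States for t in [t_start, t_end], backtracked from ``last`` at t_end."""
    out = np.empty(t_end - t_start + 1, dtype=np.int64)
    s = last
    for t in range(t_end, t_start - 1, -1):
        out[t - t_start] = s
        if t > t_start:
            s = psi[t, s]
    return out


def viterbi(params: HmmParams, obs: np.ndarray,
            logB: Optional[np.ndarray] = None) -> DecodeResult:
    """Exact offline Viterbi decoding with forward-backward posteriors."""
    if logB is None:
        logB = log_emission_matrix(params, obs)
    logA = _log_mask(params.A)
    logpi = _log_mask(params.pi)
    delta, psi = _viterbi_trellis(logpi, logA, logB)
    T = logB.shape[0]
    last = int(np.argmax(delta[-1]))
    states = _backtrack(psi, last, T - 1, 0)
    gamma, loglik = forward_backward(params, obs, logB)
    return DecodeResult(states=states, gamma=gamma, loglik=loglik)


def fixed_lag_viterbi(params: HmmParams, obs: np.ndarray,
                      lag_samples: int) -> DecodeResult:
    """Fixed-lag (online) Viterbi: emit the state ``lag`` samples behind.

    At each step ``t`` the best partial path ending anywhere at ``t`` is
    backtracked and its state at ``t - lag`` is committed. For
    ``lag >= T`` the output equals exact Viterbi.
    """
    if lag_samples < 1:
        raise ValueError("lag must be >= 1 sample")
    logB = log_emission_matrix(params, obs)
    logA = _log_mask(params.A)
    logpi = _log_mask(params.pi)
    delta, psi = _viterbi_trellis(logpi, logA, logB)
    T = logB.shape[0]
    states = np.empty(T, dtype=np.int64)
    for t in range(T):
        if t - lag_samples < 0:
            continue
        best = int(np.argmax(delta[t]))
        states[t - lag_samples] = _backtrack(psi, best, t, t - lag_samples)[0]
    # flush the tail (and the whole sequence when lag >= T) from the final column
    best = int(np.argmax(delta[-1]))
    tail_start = max(T - lag_samples, 0)
    states[tail_start:] = _backtrack(psi, best, T - 1, tail_start)
    gamma, loglik = forward_backward(params, obs, logB)
    return DecodeResult(states=states, gamma=gamma, loglik=loglik)


def path_logjoint(params: HmmParams, obs: np.ndarray, states: np.ndarray) -> float:
    """Log joint probability of a state path and the observations."""
    logB = log_emission_matrix(params, obs)
    logA = _log_mask(params.A)
    logpi = _log_mask(params.pi)
    states = np.asarray(states, dtype=int)
    ll = logpi[states[0]] + logB[0, states[0]]
    for t in range(1, states.size):
        ll += logA[states[t - 1], states[t]] + logB[t, states[t]]
    return float(ll)


def sample(params: HmmParams, n_samples: int,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw a state path and observations from the model."""
    n = params.n_states
    states = np.empty(n_samples, dtype=np.int64)
    obs = np.empty(n_samples)
    s = rng.choice(n, p=params.pi)
    for t in range(n_samples):
        states[t] = s
        k = rng.choice(params.n_mix, p=params.w[s])
        obs[t] = rng.normal(params.mu[s, k], params.sigma[s, k])
        s = rng.choice(n, p=params.A[s])
    return states, obs
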