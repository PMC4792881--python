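"""Discretized-observation hidden Markov model of vigilance dynamics.

The model is a 3-state Markov chain (WAKE, NREM, REM) whose observations are
the discrete symbols produced by quantizing feature vectors against a k-means
codebook. Because the observation space is a small set of learned centroids
rather than a parametric density or a fixed binning of the feature space, the
emission model is simply a 3 x M table of conditional symbol probabilities —
a *discretized*-observation HMM.

Parameters are initialized from relative frequencies of the staged training
data (transition counts for A, per-state symbol counts for B) and optionally
refined by Baum–Welch expectation–maximization. Decoding uses the Viterbi
algorithm in log space; the forward pass and Baum–Welch use the standard
scaled (normalized) recursions for numerical stability.

All probability rows are floored at a small constant and renormalized so that
out-of-sample symbols or unobserved transitions never receive exactly zero
probability, which would otherwise make every path impossible during
out-of-sample decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._types import N_STATES, STATES, Hypnogram, InvalidSymbolError
from .clustering import ObservationCodebook

__all__ = [
    "DiscretizedHMM",
    "init_hmm",
    "forward_loglik",
    "baum_welch",
    "viterbi",
    "sample_hmm",
]

PROB_FLOOR = 1e-6


def _floor_and_normalize(p: np.ndarray, floor: float) -> np.ndarray:
    p = np.maximum(np.asarray(p, dtype=float), floor)
    return p / p.sum(axis=-1, keepdims=True)


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Left eigenvector of A for eigenvalue 1, normalized to sum to 1."""
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class DiscretizedHMM:
    """HMM over 3 vigilance states emitting codebook symbols.

    ``pi``: initial state distribution (length 3); ``A``: 3 x 3 transition
    matrix; ``B``: 3 x M conditional distribution of symbols given state.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray
    codebook: ObservationCodebook | None = None
    state_order: tuple[str, ...] = STATES
    floor: float = PROB_FLOOR
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.pi.shape != (N_STATES,) or self.A.shape != (N_STATES, N_STATES):
            raise ValueError("pi must be length 3 and A 3x3")
        if self.B.ndim != 2 or self.B.shape[0] != N_STATES:
            raise ValueError("B must be 3 x M")

    @property
    def M(self) -> int:
        return int(self.B.shape[1])

    def _check_symbols(self, symbols: np.ndarray) -> np.ndarray:
        s = np.asarray(symbols, dtype=np.int64)
        if s.size and (s.min() < 0 or s.max() >= self.M):
            raise InvalidSymbolError(
                f"symbols must lie in [0, {self.M - 1}]; got range "
                f"[{s.min()}, {s.max()}]"
            )
        return s


def init_hmm(
    symbols: np.ndarray,
    states: Hypnogram,
    codebook: ObservationCodebook | None = None,
    floor: float = PROB_FLOOR,
    pi_mode: str = "stationary",
) -> DiscretizedHMM:
    """Initial HMM from relative frequencies of a staged training sequence.

    ``A[i, j]`` is the fraction of transitions out of state i that land in j;
    ``B[i, m]`` the fraction of state-i epochs emitting symbol m. Rows are
    floored and renormalized. A state absent from the training labels gets a
    uniform row (with a warning). ``pi`` defaults to the stationary
    distribution of A (``pi_mode="stationary"``); ``pi_mode="first"`` uses a
    point mass on the first observed state instead.
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    labels = states.labels
    if symbols.size != labels.size:
        raise ValueError("symbols and states must have equal length")
    if labels.size < 2:
        raise ValueError("need at least 2 epochs to count transitions")
    M = int(symbols.max()) + 1 if codebook is None else codebook.M
    if symbols.min() < 0 or symbols.max() >= M:
        raise InvalidSymbolError(f"symbols must lie in [0, {M - 1}]")

    A = np.zeros((N_STATES, N_STATES))
    np.add.at(A, (labels[:-1], labels[1:]), 1.0)
    B = np.zeros((N_STATES, M))
    np.add.at(B, (labels, symbols), 1.0)

    for i in range(N_STATES):
        if not np.any(labels == i):
            warnings.warn(
                f"state {STATES[i]} absent from training labels; using uniform rows",
                stacklevel=2,
            )
            A[i] = 1.0
            B[i] = 1.0
        else:
            if A[i].sum() == 0:  # state occurs only at the final epoch
                A[i] = 1.0
    A = _floor_and_normalize(A, floor)
    B = _floor_and_normalize(B, floor)

    if pi_mode == "stationary":
        pi = stationary_distribution(A)
    elif pi_mode == "first":
        pi = np.zeros(N_STATES)
        pi[labels[0]] = 1.0
        pi = _floor_and_normalize(pi, floor)
    else:
        raise ValueError("pi_mode must be 'stationary' or 'first'")
    return DiscretizedHMM(pi=pi, A=A, B=B, codebook=codebook, floor=floor)


def _forward_scaled(
    hmm: DiscretizedHMM, symbols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward pass. Returns (alpha_hat [T x 3], scales c [T])."""
    T = symbols.size
    alpha = np.empty((T, N_STATES))
    c = np.empty(T)
    a = hmm.pi * hmm.B[:, symbols[0]]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ hmm.A) * hmm.B[:, symbols[t]]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    return alpha, c


def _backward_scaled(
    hmm: DiscretizedHMM, symbols: np.ndarray, c: np.ndarray
) -> np.ndarray:
    T = symbols.size
    beta = np.empty((T, N_STATES))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (hmm.A @ (hmm.B[:, symbols[t + 1]] * beta[t + 1])) / c[t + 1]
    return beta


def forward_loglik(hmm: DiscretizedHMM, symbols: np.ndarray) -> float:
    """Exact log P(symbols | hmm) via the scaled forward recursion."""
    s = hmm._check_symbols(symbols)
    if s.size == 0:
        return 0.0
    _, c = _forward_scaled(hmm, s)
    return float(np.log(c).sum())


def baum_welch(
    hmm: DiscretizedHMM,
    symbols: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    update_pi: bool = True,
) -> tuple[DiscretizedHMM, np.ndarray]:
    """Baum–Welch EM refinement of (pi, A, B).

    Scaled forward–backward E-step, closed-form M-step, iterating until the
    relative log-likelihood improvement drops below ``tol`` or ``max_iter``
    iterations. Rows are floored and renormalized after every M-step. Returns
    the refined model and the per-iteration log-likelihood trace (evaluated
    at the start of each iteration, plus a final entry for the returned
    model); the trace is non-decreasing up to the tiny perturbation of the
    probability floor.
    """
    s = hmm._check_symbols(symbols)
    if s.size < 2:
        raise ValueError("Baum-Welch needs at least 2 observations")
    pi, A, B = hmm.pi.copy(), hmm.A.copy(), hmm.B.copy()
    floor = hmm.floor
    M = hmm.M
    trace: list[float] = []
    onehot = np.zeros((s.size, M))
    onehot[np.arange(s.size), s] = 1.0

    for _ in range(max_iter):
        cur = DiscretizedHMM(pi=pi, A=A, B=B, floor=floor)
        alpha, c = _forward_scaled(cur, s)
        ll = float(np.log(c).sum())
        trace.append(ll)
        beta = _backward_scaled(cur, s, c)

        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        # xi summed over t: E[number of i->j transitions]
        w = (B[:, s[1:]] * beta[1:].T) / c[1:]  # 3 x (T-1)
        xi_sum = A * (alpha[:-1].T @ w.T)

        new_pi = gamma[0] if update_pi else pi
        new_A = _floor_and_normalize(xi_sum, floor)
        new_B = _floor_and_normalize(gamma.T @ onehot, floor)
        pi = _floor_and_normalize(new_pi, floor) if update_pi else pi
        A, B = new_A, new_B

        if len(trace) >= 2:
            prev = trace[-2]
            if (ll - prev) < tol * max(1.0, abs(prev)):
                break

    refined = DiscretizedHMM(
        pi=pi, A=A, B=B, codebook=hmm.codebook, floor=floor,
        meta={**hmm.meta, "baum_welch_iterations": len(trace), "tol": tol},
    )
    trace.append(forward_loglik(refined, s))
    return refined, np.asarray(trace)


def viterbi(
    hmm: DiscretizedHMM, symbols: np.ndarray, epoch_s: float = 4.0
) -> tuple[Hypnogram, float]:
    """Most probable state path, decoded in log space with backtracking.

    Ties break toward the state earliest in (WAKE, NREM, REM). The returned
    log-probability is log pi + sum(log A) + sum(log B) along the decoded
    path.
    """
    s = hmm._check_symbols(symbols)
    if s.size == 0:
        raise ValueError("cannot decode an empty symbol sequence")
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.pi)
        log_A = np.log(hmm.A)
        log_B = np.log(hmm.B)
    T = s.size
    delta = np.empty((T, N_STATES))
    psi = np.zeros((T, N_STATES), dtype=np.int64)
    delta[0] = log_pi + log_B[:, s[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_A  # prev x next
        psi[t] = np.argmax(cand, axis=0)  # first max -> earliest state
        delta[t] = cand[psi[t], np.arange(N_STATES)] + log_B[:, s[t]]
    best_end = int(np.argmax(delta[-1]))
    if not np.isfinite(delta[-1, best_end]):
        raise InvalidSymbolError("no state path has nonzero probability")
    path = np.empty(T, dtype=np.int64)
    path[-1] = best_end
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return Hypnogram(labels=path, epoch_s=epoch_s), float(delta[-1, best_end])


def sample_hmm(
    hmm: DiscretizedHMM, T: int, seed: int = 0, epoch_s: float = 4.0
) -> tuple[Hypnogram, np.ndarray]:
    """Draw a state path from (pi, A) and symbols from B. Deterministic per seed."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.empty(T, dtype=np.int64)
    symbols = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(N_STATES, p=hmm.pi / hmm.pi.sum())
    for t in range(1, T):
        states[t] = rng.choice(N_STATES, p=hmm.A[states[t - 1]])
    M = hmm.M
    for t in range(T):
        symbols[t] = rng.choice(M, p=hmm.B[states[t]])
    return Hypnogram(labels=states, epoch_s=epoch_s), symbols
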