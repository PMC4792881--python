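"""Shared fixtures and independent oracles.

The brute-force oracles here enumerate all 3^T state paths directly from the
model parameters; they share no code with the scaled/log-space recursions
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sleepseg import DiscretizedHMM


def random_hmm(rng: np.random.Generator, M: int) -> DiscretizedHMM:
    """Random stochastic (pi, A, B) via Dirichlet rows."""
    return DiscretizedHMM(
        pi=rng.dirichlet(np.ones(3)),
        A=rng.dirichlet(np.ones(3), size=3),
        B=rng.dirichlet(np.ones(M), size=3),
    )


def brute_force_loglik(hmm: DiscretizedHMM, symbols: np.ndarray) -> float:
    """log P(symbols) by exhaustive sum over all state paths."""
    total = 0.0
    T = len(symbols)
    for path in itertools.product(range(3), repeat=T):
        p = hmm.pi[path[0]] * hmm.B[path[0], symbols[0]]
        for t in range(1, T):
            p *= hmm.A[path[t - 1], path[t]] * hmm.B[path[t], symbols[t]]
        total += p
    return float(np.log(total))


def brute_force_viterbi(
    hmm: DiscretizedHMM, symbols: np.ndarray
) -> tuple[list[tuple[int, ...]], float]:
    """All argmax paths and the max path log-probability, by enumeration."""
    T = len(symbols)
    best_lp = -np.inf
    best_paths: list[tuple[int, ...]] = []
    with np.errstate(divide="ignore"):
        lpi, lA, lB = np.log(hmm.pi), np.log(hmm.A), np.log(hmm.B)
    for path in itertools.product(range(3), repeat=T):
        lp = lpi[path[0]] + lB[path[0], symbols[0]]
        for t in range(1, T):
            lp += lA[path[t - 1], path[t]] + lB[path[t], symbols[t]]
        if lp > best_lp + 1e-12:
            best_lp, best_paths = lp, [path]
        elif abs(lp - best_lp) <= 1e-12:
            best_paths.append(path)
    return best_paths, float(best_lp)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
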