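"""HMM estimation and decoding against counting, enumeration and EM oracles."""

import numpy as np
import pytest

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm
from sleepseg import (
    NREM,
    WAKE,
    DiscretizedHMM,
    Hypnogram,
    InvalidSymbolError,
    baum_welch,
    forward_loglik,
    init_hmm,
    sample_hmm,
    stationary_distribution,
    viterbi,
)


def hyp(labels):
    return Hypnogram(labels=np.asarray(labels), epoch_s=4.0)


class TestInit:
    def test_transition_counting_by_hand(self):
        # W,W,N,N,W: from W -> {W, N}, from N -> {N, W}
        h = hyp([0, 0, 1, 1, 0])
        m = init_hmm(np.zeros(5, dtype=int), h)
        assert m.A[0, :2] == pytest.approx([0.5, 0.5], abs=1e-5)
        assert m.A[1, :2] == pytest.approx([0.5, 0.5], abs=1e-5)
        assert m.A[0, 2] < 1e-5 and m.A[1, 2] < 1e-5

    def test_emission_point_mass(self):
        h = hyp([0, 0, 0, 0])
        with pytest.warns(UserWarning):  # NREM and REM absent
            m = init_hmm(np.zeros(4, dtype=int), h)
        assert m.B[0, 0] > 1 - 1e-5

    def test_rows_are_stochastic(self, rng):
        h = hyp(rng.integers(0, 3, 500))
        m = init_hmm(rng.integers(0, 6, 500), h)
        assert np.allclose(m.pi.sum(), 1, atol=1e-12)
        assert np.allclose(m.A.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(m.B.sum(axis=1), 1, atol=1e-12)

    def test_long_chain_recovers_generator(self, rng):
        gen = DiscretizedHMM(
            pi=np.array([0.4, 0.5, 0.1]),
            A=np.array([[0.95, 0.04, 0.01], [0.03, 0.95, 0.02], [0.1, 0.05, 0.85]]),
            B=rng.dirichlet(np.ones(5), 3),
        )
        states, symbols = sample_hmm(gen, 20_000, seed=11)
        est = init_hmm(symbols, states)
        assert np.max(np.abs(est.A - gen.A)) < 0.02

    def test_pi_is_stationary_of_A(self, rng):
        h = hyp(rng.integers(0, 3, 400))
        m = init_hmm(rng.integers(0, 4, 400), h)
        assert np.allclose(m.pi @ m.A, m.pi, atol=1e-9)


class TestForward:
    def test_t1_uniform_closed_form(self):
        M = 6
        m = DiscretizedHMM(pi=np.ones(3) / 3, A=np.ones((3, 3)) / 3,
                           B=np.ones((3, M)) / M)
        assert forward_loglik(m, np.array([2])) == pytest.approx(np.log(1 / M))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 6))
        T = int(rng.integers(2, 9))
        m = random_hmm(rng, M)
        symbols = rng.integers(0, M, T)
        assert forward_loglik(m, symbols) == pytest.approx(
            brute_force_loglik(m, symbols), rel=1e-10
        )

    def test_deterministic_cycle(self):
        A = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        B = np.eye(3)
        m = DiscretizedHMM(pi=np.array([0.5, 0.25, 0.25]), A=A, B=B)
        symbols = np.array([0, 1, 2, 0, 1])  # the only possible path from 0
        assert forward_loglik(m, symbols) == pytest.approx(np.log(0.5))

    def test_invalid_symbol_raises(self):
        m = DiscretizedHMM(pi=np.ones(3) / 3, A=np.ones((3, 3)) / 3,
                           B=np.ones((3, 4)) / 4)
        with pytest.raises(InvalidSymbolError):
            forward_loglik(m, np.array([0, 4]))


class TestBaumWelch:
    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_trace_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        gen = random_hmm(rng, 5)
        _, symbols = sample_hmm(gen, 1500, seed=seed)
        start = random_hmm(rng, 5)
        refined, trace = baum_welch(start, symbols, max_iter=100)
        assert np.all(np.diff(trace) >= -1e-9)
        assert np.allclose(refined.pi.sum(), 1, atol=1e-12)
        assert np.allclose(refined.A.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(refined.B.sum(axis=1), 1, atol=1e-12)

    def test_start_at_generator_barely_moves(self):
        # balanced chain and T=40000 keep every state's visit count large
        # enough that the ML estimate sits within 0.02 of the generator
        gen = DiscretizedHMM(
            pi=np.ones(3) / 3,
            A=np.array([[0.92, 0.05, 0.03], [0.04, 0.92, 0.04], [0.05, 0.04, 0.91]]),
            B=np.array(
                [
                    [0.7, 0.1, 0.1, 0.1],
                    [0.1, 0.7, 0.1, 0.1],
                    [0.1, 0.1, 0.7, 0.1],
                ]
            ),
        )
        _, symbols = sample_hmm(gen, 40_000, seed=5)
        refined, _ = baum_welch(gen, symbols, max_iter=300)
        assert np.max(np.abs(refined.A - gen.A)) < 0.02
        assert np.max(np.abs(refined.B - gen.B)) < 0.02

    def test_constant_symbols_converge_to_point_mass(self, rng):
        start = random_hmm(rng, 4)
        symbols = np.full(300, 2)
        refined, _ = baum_welch(start, symbols, max_iter=200)
        assert np.all(refined.B[:, 2] >= 0.99)

    def test_cross_check_against_hmmlearn(self):
        # independent reference implementation of the same EM objective
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(42)
        gen = random_hmm(rng, 4)
        _, symbols = sample_hmm(gen, 800, seed=42)
        ours = forward_loglik(gen, symbols)
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = gen.pi, gen.A, gen.B
        theirs = ref.score(symbols.reshape(-1, 1))
        assert ours == pytest.approx(theirs, rel=1e-10)


class TestViterbi:
    def test_identity_emissions_read_off_states(self, rng):
        A = rng.dirichlet(np.ones(3) * 5, 3)
        m = DiscretizedHMM(pi=np.ones(3) / 3, A=A, B=np.eye(3))
        symbols = rng.integers(0, 3, 50)
        path, _ = viterbi(m, symbols)
        assert np.array_equal(path.labels, symbols)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(1000 + seed)
        M = int(rng.integers(2, 6))
        T = int(rng.integers(2, 9))
        m = random_hmm(rng, M)
        symbols = rng.integers(0, M, T)
        path, lp = viterbi(m, symbols)
        best_paths, best_lp = brute_force_viterbi(m, symbols)
        assert lp == pytest.approx(best_lp, abs=1e-10)
        if len(best_paths) == 1:
            assert tuple(path.labels) == best_paths[0]

    def test_all_uniform_ties_to_wake(self):
        m = DiscretizedHMM(pi=np.ones(3) / 3, A=np.ones((3, 3)) / 3,
                           B=np.ones((3, 4)) / 4)
        path, _ = viterbi(m, np.array([0, 1, 2, 3]))
        assert np.all(path.labels == WAKE)

    def test_permutation_equivariance(self, rng):
        m = random_hmm(rng, 5)
        symbols = rng.integers(0, 5, 200)
        path, lp = viterbi(m, symbols)
        perm = np.array([2, 0, 1])  # new index of old state i is perm[i]
        inv = np.argsort(perm)
        pm = DiscretizedHMM(
            pi=m.pi[inv], A=m.A[np.ix_(inv, inv)], B=m.B[inv]
        )
        ppath, plp = viterbi(pm, symbols)
        assert plp == pytest.approx(lp, abs=1e-9)
        assert np.array_equal(ppath.labels, perm[path.labels])


class TestSampling:
    def test_absorbing_chain_stays_put(self):
        m = DiscretizedHMM(pi=np.array([0, 1, 0]), A=np.eye(3),
                           B=np.ones((3, 2)) / 2)
        states, _ = sample_hmm(m, 100, seed=0)
        assert np.all(states.labels == NREM)

    def test_symbol_frequencies_match_stationary_mixture(self):
        rng = np.random.default_rng(3)
        m = random_hmm(rng, 4)
        _, symbols = sample_hmm(m, 50_000, seed=3)
        pi_stat = stationary_distribution(m.A)
        expected = pi_stat @ m.B
        freqs = np.bincount(symbols, minlength=4) / symbols.size
        assert np.max(np.abs(freqs - expected)) < 0.01

    def test_seed_determinism(self, rng):
        m = random_hmm(rng, 3)
        a = sample_hmm(m, 200, seed=9)
        b = sample_hmm(m, 200, seed=9)
        c = sample_hmm(m, 200, seed=10)
        assert np.array_equal(a[0].labels, b[0].labels)
        assert np.array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])
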