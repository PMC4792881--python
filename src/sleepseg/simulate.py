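"""Ground-truthed synthetic data at every pipeline level.

Generators produce (i) vigilance-state hypnograms from a diagonal-dominant
3-state Markov chain, (ii) smoothed-log feature triplets drawn from
state-conditioned Gaussians whose geometry mimics real mouse recordings
(Wake: high EMG tone; NREM: low EMG, delta-dominant EEG; REM: low EMG,
theta-dominant EEG with relatively more high-band power), and (iii) raw
EEG/EMG sample streams whose band-power contrasts realize the same states
(NREM: 2 Hz sinusoid; REM: 7 Hz; Wake: 12 Hz plus strong EMG noise).

Every generator is a pure function of its parameters and seed. The default
chain preset yields light-period-like state proportions of roughly
35/55/10% Wake/NREM/REM with mean dwell times of a few minutes; a second
preset emulates the dark period (mice mostly awake, REM near 1%), the regime
in which unsupervised staging is known to degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import NREM, REM, WAKE, FeatureSeries, Hypnogram, SignalRecording
from .hmm import stationary_distribution

__all__ = [
    "StateFeatureModel",
    "VigilanceChain",
    "LIGHT_CHAIN",
    "DARK_CHAIN",
    "DEFAULT_FEATURE_MODEL",
    "simulate_hypnogram",
    "simulate_features",
    "simulate_raw",
    "simulate_cohort",
]


@dataclass
class StateFeatureModel:
    """State-conditioned Gaussian feature distributions (smoothed-log scale).

    ``means`` is 3 x 3 (state rows in WAKE/NREM/REM order, feature columns in
    emg_rms/dt_ratio/hl_ratio order); ``sds`` the matching per-feature
    standard deviations (diagonal covariance).
    """

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != (3, 3) or self.sds.shape != (3, 3):
            raise ValueError("means and sds must be 3 x 3")
        if np.any(self.sds < 0):
            raise ValueError("standard deviations must be non-negative")


@dataclass
class VigilanceChain:
    """3-state Markov chain of vigilance states."""

    A_true: np.ndarray
    pi_true: np.ndarray | None = None  # default: stationary distribution

    def __post_init__(self) -> None:
        self.A_true = np.asarray(self.A_true, dtype=float)
        if self.A_true.shape != (3, 3):
            raise ValueError("A_true must be 3 x 3")
        if not np.allclose(self.A_true.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of A_true must sum to 1")
        if self.pi_true is None:
            self.pi_true = stationary_distribution(self.A_true)
        else:
            self.pi_true = np.asarray(self.pi_true, dtype=float)


#: Light-period-like chain: stationary proportions ~ (0.35, 0.55, 0.10) W/N/R,
#: dwell times of a few minutes (4-s epochs).
LIGHT_CHAIN = VigilanceChain(
    A_true=np.array(
        [
            [0.974, 0.025, 0.001],
            [0.008, 0.983, 0.009],
            [0.045, 0.005, 0.950],
        ]
    )
)

#: Dark-period-like chain: mice mostly awake, REM ~1% — the regime where
#: unsupervised models see too little REM to estimate it well.
DARK_CHAIN = VigilanceChain(
    A_true=np.array(
        [
            [0.9890, 0.0107, 0.0003],
            [0.0300, 0.9665, 0.0035],
            [0.0800, 0.0100, 0.9100],
        ]
    )
)

#: Cluster geometry on the smoothed-log scale: Wake separated from sleep by
#: the EMG axis (~6 sd), NREM from REM by the delta/theta axis (~10 sd), with
#: REM carrying relatively more high-band EEG power. Separable but
#: overlapping at the default sd of 0.35.
DEFAULT_FEATURE_MODEL = StateFeatureModel(
    means=np.array(
        [
            [1.0, 0.0, 0.0],  # WAKE: high muscle tone, mixed EEG
            [-1.2, 2.0, -1.5],  # NREM: atonia, delta-dominant
            [-1.2, -1.5, 0.5],  # REM: atonia, theta-dominant, high hi/lo
        ]
    ),
    sds=np.full((3, 3), 0.35),
)


def simulate_hypnogram(
    chain: VigilanceChain, T: int, seed: int = 0, epoch_s: float = 4.0
) -> Hypnogram:
    """Sample a length-T state sequence from the chain. Deterministic per seed."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling with precomputed row CDFs (fast for long T)
    cdf = np.cumsum(chain.A_true, axis=1)
    u = rng.random(T)
    states = np.empty(T, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(chain.pi_true), u[0], side="right")
    for t in range(1, T):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t], side="right")
    np.clip(states, 0, 2, out=states)
    return Hypnogram(labels=states, epoch_s=epoch_s)


def simulate_features(
    h: Hypnogram, sfm: StateFeatureModel | None = None, seed: int = 0
) -> FeatureSeries:
    """Draw one feature triplet per epoch from the epoch state's Gaussian."""
    sfm = sfm or DEFAULT_FEATURE_MODEL
    rng = np.random.default_rng(seed)
    T = len(h)
    draws = sfm.means[h.labels] + rng.standard_normal((T, 3)) * sfm.sds[h.labels]
    return FeatureSeries(
        emg_rms=draws[:, 0],
        dt_ratio=draws[:, 1],
        hl_ratio=draws[:, 2],
        epoch_s=h.epoch_s,
        stage="smoothed_log",
    )


# raw-signal generator presets: state -> (eeg freq Hz, eeg amplitude), EMG sd
_EEG_TONES = {WAKE: (12.0, 1.0), NREM: (2.0, 3.0), REM: (7.0, 2.0)}
_EMG_SD = {WAKE: 2.0, NREM: 0.3, REM: 0.3}
_EEG_NOISE_SD = 0.5


def simulate_raw(h: Hypnogram, fs: float = 400.0, seed: int = 0) -> SignalRecording:
    """Synthesize raw EEG/EMG sample streams realizing the hypnogram's states.

    EEG per epoch: a state-dependent sinusoid (NREM 2 Hz amp 3; REM 7 Hz
    amp 2; Wake 12 Hz amp 1) plus white noise (sd 0.5), with phase continuous
    across the recording. EMG: white noise with state-dependent amplitude
    (Wake 2.0, sleep 0.3) band-limited to 10-100 Hz, mimicking the hardware
    filtering of a typical EMG front end.
    """
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz to contain the EMG band")
    from .features import bandpass  # local import avoids a cycle at import time

    rng = np.random.default_rng(seed)
    spe = int(round(fs * h.epoch_s))
    T = len(h)
    n = T * spe
    t = np.arange(n) / fs
    freqs = np.array([_EEG_TONES[s][0] for s in range(3)])
    amps = np.array([_EEG_TONES[s][1] for s in range(3)])
    per_sample_state = np.repeat(h.labels, spe)
    eeg = amps[per_sample_state] * np.sin(
        2 * np.pi * freqs[per_sample_state] * t
    ) + _EEG_NOISE_SD * rng.standard_normal(n)
    emg_sd = np.array([_EMG_SD[s] for s in range(3)])
    emg_white = emg_sd[per_sample_state] * rng.standard_normal(n)
    emg = bandpass(emg_white, fs, 10.0, min(100.0, fs / 2 - 1.0), 3)
    return SignalRecording(eeg=eeg, emg=emg, fs=fs)


def _jitter_chain(
    chain: VigilanceChain, jitter: float, rng: np.random.Generator
) -> VigilanceChain:
    A = chain.A_true.copy()
    off = ~np.eye(3, dtype=bool)
    A[off] = A[off] * (1.0 + jitter * rng.uniform(-1, 1, size=off.sum()))
    A[np.arange(3), np.arange(3)] = 0.0
    A[np.arange(3), np.arange(3)] = 1.0 - A.sum(axis=1)
    return VigilanceChain(A_true=A)


def _jitter_features(
    sfm: StateFeatureModel, jitter: float, rng: np.random.Generator
) -> StateFeatureModel:
    means = sfm.means * (1.0 + jitter * rng.uniform(-1, 1, size=(3, 3)))
    sds = sfm.sds * (1.0 + jitter * rng.uniform(-1, 1, size=(3, 3)))
    return StateFeatureModel(means=means, sds=sds)


def simulate_cohort(
    n_subjects: int,
    T: int,
    seeds: list[int] | None = None,
    jitter: float = 0.05,
    chain: VigilanceChain | None = None,
    sfm: StateFeatureModel | None = None,
    noise_scale: float = 1.0,
    epoch_s: float = 4.0,
) -> list[tuple[Hypnogram, FeatureSeries]]:
    """Per-subject (hypnogram, features) pairs jittered around the presets.

    Each subject's chain off-diagonals and feature means/sds are perturbed
    multiplicatively by up to ``jitter``; ``noise_scale`` multiplies the
    feature standard deviations uniformly (used to study noisy regimes).
    ``seeds`` must provide one seed per subject (default: 0..n-1).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seeds is None:
        seeds = list(range(n_subjects))
    if len(seeds) < n_subjects:
        raise ValueError(f"need {n_subjects} seeds, got {len(seeds)}")
    chain = chain or LIGHT_CHAIN
    sfm = sfm or DEFAULT_FEATURE_MODEL
    out = []
    for i in range(n_subjects):
        rng = np.random.default_rng(seeds[i])
        sub_chain = _jitter_chain(chain, jitter, rng) if jitter > 0 else chain
        sub_sfm = _jitter_features(sfm, jitter, rng) if jitter > 0 else sfm
        sub_sfm = StateFeatureModel(
            means=sub_sfm.means, sds=sub_sfm.sds * noise_scale
        )
        h = simulate_hypnogram(sub_chain, T, seed=seeds[i] + 10_000, epoch_s=epoch_s)
        f = simulate_features(h, sub_sfm, seed=seeds[i] + 20_000)
        out.append((h, f))
    return out
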