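"""Core domain containers shared across the pipeline.

Vigilance states are encoded as small integers in a fixed order
(WAKE=0, NREM=1, REM=2); all tie-breaking rules resolve toward the
earliest state in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed vigilance-state ordering used everywhere.
STATES: tuple[str, ...] = ("WAKE", "NREM", "REM")
WAKE, NREM, REM = 0, 1, 2
N_STATES = len(STATES)

STATE_TO_INDEX = {name: i for i, name in enumerate(STATES)}


class SleepSegError(Exception):
    """Base class for all package errors."""


class InvalidBandError(SleepSegError):
    """Filter band lies outside (0, Nyquist)."""


class ShortSignalError(SleepSegError):
    """Signal too short for stable filtering or epoching."""


class DegenerateInputError(SleepSegError):
    """Not enough distinct points to cluster."""


class CannotSplitSleepError(DegenerateInputError):
    """Sleep cluster has fewer than two distinct delta/theta values."""


class InvalidSymbolError(SleepSegError):
    """Observation symbol outside the codebook range."""


class AlignmentError(SleepSegError):
    """Sequences that must be aligned differ in length or epoch duration."""


@dataclass
class SignalRecording:
    """Synchronized EEG/EMG sample streams (µV) with sampling rate ``fs`` (Hz)."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays of equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.fs

    def n_epochs(self, epoch_s: float) -> int:
        return int(self.eeg.size // round(self.fs * epoch_s))


@dataclass
class FeatureSeries:
    """Per-epoch feature triplet: EMG r.m.s., delta/theta ratio, high/low ratio.

    ``stage`` is ``"raw"`` directly after extraction (strictly positive powers)
    or ``"smoothed_log"`` after the moving average and log transform.
    """

    emg_rms: np.ndarray
    dt_ratio: np.ndarray
    hl_ratio: np.ndarray
    epoch_s: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.emg_rms = np.asarray(self.emg_rms, dtype=float)
        self.dt_ratio = np.asarray(self.dt_ratio, dtype=float)
        self.hl_ratio = np.asarray(self.hl_ratio, dtype=float)
        n = self.emg_rms.size
        if self.dt_ratio.size != n or self.hl_ratio.size != n:
            raise ValueError("feature sequences must have equal length")
        if self.epoch_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.stage not in ("raw", "smoothed_log"):
            raise ValueError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return int(self.emg_rms.size)

    def as_matrix(self) -> np.ndarray:
        """Epochs x 3 matrix in the order (emg_rms, dt_ratio, hl_ratio)."""
        return np.column_stack([self.emg_rms, self.dt_ratio, self.hl_ratio])


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels over {WAKE, NREM, REM}."""

    labels: np.ndarray  # int codes into STATES
    epoch_s: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.dtype.kind in "US":
            labels = np.array([STATE_TO_INDEX[str(s)] for s in labels])
        self.labels = labels.astype(np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if self.epoch_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.labels.min() < 0 or self.labels.max() >= N_STATES:
            raise ValueError("labels must be codes in [0, 2] or state names")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def names(self) -> list[str]:
        return [STATES[i] for i in self.labels]

    @property
    def duration_s(self) -> float:
        return self.labels.size * self.epoch_s


@dataclass
class FeatureConfig:
    """Feature-extraction settings.

    Defaults follow standard rodent polysomnography practice: 4-s epochs,
    muscle tone from 80–100 Hz EMG, EEG band ratios delta (0.5–4 Hz) over
    theta (6–9 Hz) and high (9–45 Hz) over low (0.5–9 Hz), a 3rd-order
    Butterworth filter for every band, and a 4-epoch (16 s) trailing moving
    average applied before the natural-log transform.
    """

    epoch_s: float = 4.0
    emg_band: tuple[float, float] = (80.0, 100.0)
    delta_band: tuple[float, float] = (0.5, 4.0)
    theta_band: tuple[float, float] = (6.0, 9.0)
    hi_band: tuple[float, float] = (9.0, 45.0)
    lo_band: tuple[float, float] = (0.5, 9.0)
    filter_order: int = 3
    smooth_window: int = 4
    log_before_smooth: bool = False  # default order: smooth, then log
    power_floor: float = 1e-12  # squared-µV floor for denominators / pre-log

    def validate(self, fs: float) -> None:
        for name in ("emg_band", "delta_band", "theta_band", "hi_band", "lo_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise InvalidBandError(f"{name}: need 0 < lo < hi, got ({lo}, {hi})")
            if hi >= fs / 2:
                raise InvalidBandError(
                    f"{name}: high edge {hi} Hz is at or above Nyquist ({fs / 2} Hz)"
                )
        if self.epoch_s <= 0 or round(self.epoch_s * fs) < 1:
            raise ValueError("epoch_s x fs must be a positive number of samples")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
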