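"""EEG/EMG band-power feature extraction.

Three features summarize each scoring epoch:

* ``emg_rms`` — r.m.s. of the 80–100 Hz band-passed EMG (muscle tone;
  separates Wake from sleep),
* ``dt_ratio`` — mean-squared EEG power in the delta band (0.5–4 Hz) over
  the theta band (6–9 Hz) (separates NREM from REM),
* ``hl_ratio`` — mean-squared EEG power in 9–45 Hz over 0.5–9 Hz
  (further distinguishes REM).

Filtering is zero-phase (forward–backward 3rd-order Butterworth), applied
once to the whole channel before epoching so that per-epoch estimates carry
no filter transients. Each feature series is then smoothed with a trailing
moving average and natural-log transformed to reduce noise and skewness.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from ._types import (
    FeatureConfig,
    FeatureSeries,
    InvalidBandError,
    ShortSignalError,
    SignalRecording,
)

__all__ = ["bandpass", "extract_features", "smooth_and_log"]


def bandpass(
    x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    output has no phase lag relative to the input.

    Parameters
    ----------
    x : array
        Input samples.
    fs : float
        Sampling rate in Hz.
    lo, hi : float
        Band edges in Hz; must satisfy ``0 < lo < hi < fs/2``.
    order : int
        Butterworth order of the underlying one-pass filter (default 3).

    Returns
    -------
    array of the same length as ``x``.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < lo < hi < fs / 2):
        raise InvalidBandError(
            f"band ({lo}, {hi}) Hz must lie strictly inside (0, {fs / 2}) Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs padlen < len(x); require a comfortable margin
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= max(3 * order, padlen):
        raise ShortSignalError(
            f"signal of length {x.size} too short for order-{order} zero-phase filter"
        )
    return signal.sosfiltfilt(sos, x)


def _epoch_mean_square(x: np.ndarray, samples_per_epoch: int, floor: float) -> np.ndarray:
    n_epochs = x.size // samples_per_epoch
    trimmed = x[: n_epochs * samples_per_epoch]
    ms = (trimmed.reshape(n_epochs, samples_per_epoch) ** 2).mean(axis=1)
    return np.maximum(ms, floor)


def extract_features(
    rec: SignalRecording, cfg: FeatureConfig | None = None
) -> FeatureSeries:
    """Compute the raw per-epoch feature triplet from a two-channel recording.

    Each channel is band-filtered once over its full length, then cut into
    epochs of ``cfg.epoch_s`` seconds; a trailing partial epoch is discarded.
    Mean-squared power denominators are floored (``cfg.power_floor``) so a
    silent channel never produces a division error.
    """
    cfg = cfg or FeatureConfig()
    cfg.validate(rec.fs)
    spe = int(round(rec.fs * cfg.epoch_s))
    if rec.eeg.size < spe:
        raise ShortSignalError(
            f"recording of {rec.eeg.size} samples is shorter than one "
            f"{cfg.epoch_s}-s epoch ({spe} samples)"
        )
    order = cfg.filter_order
    emg_f = bandpass(rec.emg, rec.fs, *cfg.emg_band, order)
    delta = bandpass(rec.eeg, rec.fs, *cfg.delta_band, order)
    theta = bandpass(rec.eeg, rec.fs, *cfg.theta_band, order)
    hi = bandpass(rec.eeg, rec.fs, *cfg.hi_band, order)
    lo = bandpass(rec.eeg, rec.fs, *cfg.lo_band, order)

    floor = cfg.power_floor
    emg_ms = _epoch_mean_square(emg_f, spe, floor)
    return FeatureSeries(
        emg_rms=np.sqrt(emg_ms),
        dt_ratio=_epoch_mean_square(delta, spe, floor)
        / _epoch_mean_square(theta, spe, floor),
        hl_ratio=_epoch_mean_square(hi, spe, floor)
        / _epoch_mean_square(lo, spe, floor),
        epoch_s=cfg.epoch_s,
        stage="raw",
    )


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing (causal) moving average; the first window-1 terms use the
    shorter window actually available."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    start = np.maximum(idx - window + 1, 0)
    return (c[idx + 1] - c[start]) / (idx + 1 - start)


def smooth_and_log(
    feats: FeatureSeries,
    window: int = 4,
    *,
    log_before_smooth: bool = False,
    floor: float = 1e-12,
) -> FeatureSeries:
    """Trailing moving average and natural-log transform of a raw series.

    The default order is smooth-then-log; ``log_before_smooth=True`` swaps
    it. Values are floored at ``floor`` before the log, so the output is
    finite for every strictly-positive (indeed, any) raw input. Output
    length equals input length.
    """
    if feats.stage != "raw":
        raise ValueError("smooth_and_log expects a raw-stage FeatureSeries")
    if window < 1:
        raise ValueError("window must be >= 1")

    def transform(x: np.ndarray) -> np.ndarray:
        if log_before_smooth:
            return _trailing_mean(np.log(np.maximum(x, floor)), window)
        return np.log(np.maximum(_trailing_mean(x, window), floor))

    return FeatureSeries(
        emg_rms=transform(feats.emg_rms),
        dt_ratio=transform(feats.dt_ratio),
        hl_ratio=transform(feats.hl_ratio),
        epoch_s=feats.epoch_s,
        stage="smoothed_log",
    )
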