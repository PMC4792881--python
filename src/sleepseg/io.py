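"""File formats: CSV interchange, EDF signals, model/config JSON.

CSV is the canonical interchange format (mandatory headers, UTF-8, '.'
decimal, 0-based epoch indices, times in seconds from recording start).
Writers prepend a ``#``-prefixed provenance comment line; readers skip
comment lines.

EDF reading goes through :mod:`mne` when available. A minimal EDF writer
(16-bit, one data record per second) is provided for the synthetic fixture
writer, since the fixtures are generated programmatically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import (
    STATE_TO_INDEX,
    STATES,
    FeatureConfig,
    FeatureSeries,
    Hypnogram,
    SignalRecording,
)

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_edf",
    "write_edf",
    "read_features_csv",
    "write_features_csv",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "load_sample_features_mat",
    "RunConfig",
]

_VERSION = "0.1.0"


def _provenance(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"sleepseg v{_VERSION}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts) + "\n"


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


# ---------------------------------------------------------------- signals


def read_signal_csv(path: str | Path, fs: float) -> SignalRecording:
    """Two-column (eeg, emg) CSV with header; fs supplied by the caller."""
    df = pd.read_csv(path, comment="#")
    if not {"eeg", "emg"} <= set(df.columns):
        raise ValueError("signal CSV must have 'eeg' and 'emg' columns")
    return SignalRecording(eeg=df["eeg"].to_numpy(), emg=df["emg"].to_numpy(), fs=fs)


def write_signal_csv(rec: SignalRecording, path: str | Path, **prov) -> None:
    with open(path, "w") as f:
        f.write(_provenance(**prov))
        pd.DataFrame({"eeg": rec.eeg, "emg": rec.emg}).to_csv(f, index=False)


def read_edf(
    path: str | Path, eeg_channel: str = "EEG", emg_channel: str = "EMG"
) -> SignalRecording:
    """Read a two-channel recording from an EDF file (channels by label)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = {eeg_channel, emg_channel} - set(raw.ch_names)
    if missing:
        raise ValueError(f"channels {sorted(missing)} not found in {path}")
    # mne scales EDF voltages to volts internally; recover the stored units
    data = raw.get_data(picks=[eeg_channel, emg_channel]) * 1e6
    return SignalRecording(eeg=data[0], emg=data[1], fs=float(raw.info["sfreq"]))


def write_edf(
    rec: SignalRecording,
    path: str | Path,
    eeg_channel: str = "EEG",
    emg_channel: str = "EMG",
) -> None:
    """Write a two-channel 16-bit EDF file (one 1-s data record per second).

    Minimal but standard-conforming writer used by the synthetic fixture
    writer; trailing samples short of a full record are dropped.
    """
    fs = int(round(rec.fs))
    n_rec = rec.eeg.size // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one 1-s data record")
    chans = [(eeg_channel, rec.eeg[: n_rec * fs]), (emg_channel, rec.emg[: n_rec * fs])]

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = bytearray()
    header += pad("0", 8)  # version
    header += pad("X X X X", 80)  # patient id
    header += pad("Startdate X X X X", 80)  # recording id
    header += pad("01.01.00", 8) + pad("00.00.00", 8)
    header += pad(str(256 + 256 * len(chans)), 8)
    header += pad("", 44)
    header += pad(str(n_rec), 8)
    header += pad("1", 8)  # record duration, seconds
    header += pad(str(len(chans)), 4)

    phys = []
    for _, x in chans:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))

    def field_all(fmt, n):
        return b"".join(pad(fmt(i), n) for i in range(len(chans)))

    header += field_all(lambda i: chans[i][0], 16)  # label
    header += field_all(lambda i: "", 80)  # transducer
    header += field_all(lambda i: "uV", 8)  # physical dimension
    header += field_all(lambda i: f"{phys[i][0]:.6g}", 8)
    header += field_all(lambda i: f"{phys[i][1]:.6g}", 8)
    header += field_all(lambda i: "-32768", 8)
    header += field_all(lambda i: "32767", 8)
    header += field_all(lambda i: "", 80)  # prefiltering
    header += field_all(lambda i: str(fs), 8)  # samples per record
    header += field_all(lambda i: "", 32)  # reserved

    with open(path, "wb") as f:
        f.write(bytes(header))
        digital = []
        for (lo, hi), (_, x) in zip(phys, chans):
            scale = 65535 / (hi - lo)
            d = np.round((x - lo) * scale - 32768).astype("<i2")
            digital.append(d.reshape(n_rec, fs))
        for r in range(n_rec):
            for d in digital:
                f.write(d[r].tobytes())


# ---------------------------------------------------------------- features


def write_features_csv(feats: FeatureSeries, path: str | Path, **prov) -> None:
    n = len(feats)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "start_s": np.arange(n) * feats.epoch_s,
            "emg_rms": feats.emg_rms,
            "dt_ratio": feats.dt_ratio,
            "hl_ratio": feats.hl_ratio,
            "stage": feats.stage,
        }
    )
    with open(path, "w") as f:
        f.write(_provenance(**prov))
        df.to_csv(f, index=False)


def read_features_csv(path: str | Path) -> FeatureSeries:
    df = pd.read_csv(path, comment="#")
    need = {"epoch_index", "start_s", "emg_rms", "dt_ratio", "hl_ratio", "stage"}
    if not need <= set(df.columns):
        raise ValueError(f"feature CSV missing columns {sorted(need - set(df.columns))}")
    if len(df) < 2:
        epoch_s = 4.0
    else:
        epoch_s = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
    stage = str(df["stage"].iloc[0])
    return FeatureSeries(
        emg_rms=df["emg_rms"].to_numpy(),
        dt_ratio=df["dt_ratio"].to_numpy(),
        hl_ratio=df["hl_ratio"].to_numpy(),
        epoch_s=epoch_s,
        stage=stage,
    )


# --------------------------------------------------------------- hypnogram


def write_hypnogram_csv(h: Hypnogram, path: str | Path, **prov) -> None:
    n = len(h)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "start_s": np.arange(n) * h.epoch_s,
            "label": h.names,
        }
    )
    with open(path, "w") as f:
        f.write(_provenance(**prov))
        df.to_csv(f, index=False)


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, comment="#")
    if not {"epoch_index", "start_s", "label"} <= set(df.columns):
        raise ValueError("hypnogram CSV must have epoch_index,start_s,label columns")
    bad = set(df["label"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels {sorted(bad)}")
    if len(df) < 2:
        epoch_s = 4.0
    else:
        epoch_s = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
    labels = np.array([STATE_TO_INDEX[s] for s in df["label"]])
    return Hypnogram(labels=labels, epoch_s=epoch_s)


# ------------------------------------------------------------------- .mat


def load_sample_features_mat(
    path: str | Path, period: str = "light", epoch_s: float = 4.0
) -> FeatureSeries:
    """Load a supplementary feature file (.mat) with Light/Dark matrices.

    Accepts any variable whose name contains 'light'/'dark' (case-
    insensitive) and whose value is an N x 3 (or 3 x N) numeric matrix in
    (emg_rms, dt_ratio, hl_ratio) column order; the matrices are treated as
    already smoothed and log-scaled.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    key = None
    for k, v in mat.items():
        if k.startswith("__"):
            continue
        if period.lower() in k.lower() and isinstance(v, np.ndarray):
            key = k
            break
    if key is None:
        raise ValueError(f"no '{period}' feature matrix found in {path}")
    X = np.asarray(mat[key], dtype=float)
    if X.ndim != 2 or 3 not in X.shape:
        raise ValueError(f"variable {key!r} is not an N x 3 feature matrix")
    if X.shape[0] == 3 and X.shape[1] != 3:
        X = X.T
    return FeatureSeries(
        emg_rms=X[:, 0], dt_ratio=X[:, 1], hl_ratio=X[:, 2],
        epoch_s=epoch_s, stage="smoothed_log",
    )


# ----------------------------------------------------------------- config


@dataclass
class ClusterConfig:
    seed: int = 0
    restarts: int = 10
    kmin: int = 3
    kmax: int = 15
    vc_threshold: float = 0.90


@dataclass
class HMMConfig:
    tol: float = 1e-6
    max_iter: int = 500
    floor: float = 1e-6
    baum_welch: bool = True
    pi_mode: str = "stationary"


@dataclass
class RunConfig:
    """Serializable run settings for the whole pipeline."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    fs: float = 400.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        for band in ("emg_band", "delta_band", "theta_band", "hi_band", "lo_band"):
            d["features"][band] = list(d["features"][band])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fc = dict(d.get("features", {}))
        for band in ("emg_band", "delta_band", "theta_band", "hi_band", "lo_band"):
            if band in fc:
                fc[band] = tuple(fc[band])
        return cls(
            features=FeatureConfig(**fc),
            clustering=ClusterConfig(**d.get("clustering", {})),
            hmm=HMMConfig(**d.get("hmm", {})),
            fs=float(d.get("fs", 400.0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
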