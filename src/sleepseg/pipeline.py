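"""End-to-end unsupervised staging pipeline.

``fit_pipeline`` chains the unsupervised steps on a baseline recording's
smoothed-log features: two-stage k-means staging, codebook selection,
HMM initialization from relative frequencies, and (by default) Baum–Welch
refinement. The fitted bundle scores new feature data either statically
(``method="kmeans"``: nearest state centroid per epoch) or dynamically
(``method="hmm"``: quantize to codebook symbols, Viterbi-decode the state
path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._types import STATES, FeatureSeries, Hypnogram
from .clustering import (
    ObservationCodebook,
    StateClusterModel,
    assign_states,
    fit_codebook,
    fit_state_clusters,
    quantize,
)
from .hmm import DiscretizedHMM, baum_welch, init_hmm, viterbi

__all__ = ["PipelineModel", "fit_pipeline", "score"]


@dataclass
class PipelineModel:
    """Fitted staging bundle: cluster model, codebook and HMM."""

    clusters: StateClusterModel
    codebook: ObservationCodebook
    hmm: DiscretizedHMM
    epoch_s: float
    baum_welch_applied: bool
    loglik_trace: np.ndarray | None = field(default=None, repr=False)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        cb = self.codebook
        return {
            "epoch_s": self.epoch_s,
            "state_order": list(STATES),
            "baum_welch_applied": self.baum_welch_applied,
            "clusters": {
                "emg_centroids": self.clusters.emg_centroids.tolist(),
                "sleep_dt_centroids": self.clusters.sleep_dt_centroids.tolist(),
                "state_centroids": self.clusters.state_centroids.tolist(),
                "feature_mean": self.clusters.feature_mean.tolist(),
                "feature_sd": self.clusters.feature_sd.tolist(),
            },
            "codebook": {
                "centroids": cb.centroids.tolist(),
                "M": cb.M,
                "vc": cb.vc,
                "vc_threshold": cb.vc_threshold,
                "feature_mean": cb.feature_mean.tolist(),
                "feature_sd": cb.feature_sd.tolist(),
                "threshold_reached": cb.threshold_reached,
            },
            "hmm": {
                "pi": self.hmm.pi.tolist(),
                "A": self.hmm.A.tolist(),
                "B": self.hmm.B.tolist(),
                "floor": self.hmm.floor,
                "meta": self.hmm.meta,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineModel":
        cb = ObservationCodebook(
            centroids=np.array(d["codebook"]["centroids"]),
            M=int(d["codebook"]["M"]),
            vc=float(d["codebook"]["vc"]),
            vc_threshold=float(d["codebook"]["vc_threshold"]),
            feature_mean=np.array(d["codebook"]["feature_mean"]),
            feature_sd=np.array(d["codebook"]["feature_sd"]),
            threshold_reached=bool(d["codebook"]["threshold_reached"]),
        )
        clusters = StateClusterModel(
            emg_centroids=np.array(d["clusters"]["emg_centroids"]),
            sleep_dt_centroids=np.array(d["clusters"]["sleep_dt_centroids"]),
            state_centroids=np.array(d["clusters"]["state_centroids"]),
            feature_mean=np.array(d["clusters"]["feature_mean"]),
            feature_sd=np.array(d["clusters"]["feature_sd"]),
        )
        hmm = DiscretizedHMM(
            pi=np.array(d["hmm"]["pi"]),
            A=np.array(d["hmm"]["A"]),
            B=np.array(d["hmm"]["B"]),
            codebook=cb,
            floor=float(d["hmm"]["floor"]),
            meta=dict(d["hmm"].get("meta", {})),
        )
        return cls(
            clusters=clusters,
            codebook=cb,
            hmm=hmm,
            epoch_s=float(d["epoch_s"]),
            baum_welch_applied=bool(d["baum_welch_applied"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_pipeline(
    feats: FeatureSeries,
    seed: int = 0,
    kmin: int = 3,
    kmax: int = 15,
    vc_threshold: float = 0.90,
    use_baum_welch: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 10,
    pi_mode: str = "stationary",
) -> PipelineModel:
    """Fit the full unsupervised staging model on smoothed-log features."""
    clusters = fit_state_clusters(feats, seed=seed, restarts=restarts)
    codebook = fit_codebook(
        feats, kmin=kmin, kmax=kmax, vc_threshold=vc_threshold,
        seed=seed, restarts=restarts,
    )
    symbols = quantize(codebook, feats)
    states = Hypnogram(labels=clusters.training_labels, epoch_s=feats.epoch_s)
    hmm = init_hmm(symbols, states, codebook=codebook, pi_mode=pi_mode)
    trace = None
    if use_baum_welch:
        hmm, trace = baum_welch(hmm, symbols, tol=tol, max_iter=max_iter)
    return PipelineModel(
        clusters=clusters,
        codebook=codebook,
        hmm=hmm,
        epoch_s=feats.epoch_s,
        baum_welch_applied=use_baum_welch,
        loglik_trace=trace,
    )


def score(
    model: PipelineModel, feats: FeatureSeries, method: str = "hmm"
) -> Hypnogram:
    """Score feature data with a fitted model.

    ``method="kmeans"`` assigns each epoch to the nearest state centroid;
    ``method="hmm"`` quantizes to codebook symbols and Viterbi-decodes the
    most probable state path.
    """
    if method == "kmeans":
        return assign_states(model.clusters, feats)
    if method == "hmm":
        symbols = quantize(model.codebook, feats)
        h, _ = viterbi(model.hmm, symbols, epoch_s=feats.epoch_s)
        return h
    raise ValueError("method must be 'kmeans' or 'hmm'")
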