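"""Unsupervised clustering of feature epochs.

Two distinct uses of k-means live here:

1. **Vigilance staging** (``fit_state_clusters``): a two-stage, one-dimensional
   procedure — first split the EMG r.m.s. axis into Wake vs. sleep, then split
   the sleep epochs on the delta/theta axis into NREM vs. REM. State identity
   is assigned from centroid *order* (higher EMG -> Wake, higher delta/theta
   within sleep -> NREM), never from cluster index, so it is invariant to any
   monotone rescaling of an axis.
2. **Observation codebook** (``fit_codebook``): an M-centroid quantizer of the
   standardized 3-D feature space, with M the smallest value in [3, 15] whose
   explained-variance criterion exceeds a threshold (default 90%). Feature
   vectors are mapped to the nearest centroid (``quantize``), giving the
   discrete symbols a hidden Markov model consumes.

All multi-dimensional distances are computed on per-feature z-scores of the
training sample; the standardization constants are stored on the fitted
objects and reused for out-of-sample data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._types import (
    NREM,
    REM,
    STATES,
    WAKE,
    CannotSplitSleepError,
    DegenerateInputError,
    FeatureSeries,
    Hypnogram,
)

__all__ = [
    "kmeans",
    "variance_criterion",
    "StateClusterModel",
    "ObservationCodebook",
    "fit_state_clusters",
    "assign_states",
    "fit_codebook",
    "quantize",
]

DEFAULT_RESTARTS = 10
MAX_ITER = 300


def kmeans(
    points: np.ndarray, k: int, seed: int = 0, restarts: int = DEFAULT_RESTARTS
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's k-means from k-means++ seeds; best of ``restarts`` runs.

    Returns ``(centroids, labels, within_ss)``. Deterministic for a given
    seed. Raises :class:`DegenerateInputError` when there are fewer distinct
    points than clusters.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_distinct < k:
        raise DegenerateInputError(
            f"{n_distinct} distinct points cannot form {k} clusters"
        )
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=MAX_ITER,
        algorithm="lloyd",
        random_state=seed,
    ).fit(pts)
    return km.cluster_centers_, km.labels_.astype(np.int64), float(km.inertia_)


def variance_criterion(
    points: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> float:
    """Explained-variance criterion: between-cluster SS over total SS.

    Lies in [0, 1]; 1 means point-mass clusters, 0 means a single cluster
    (or all points identical, by convention).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim == 1:
        centroids = centroids[:, None]
    if labels.max(initial=-1) >= centroids.shape[0]:
        raise ValueError("labels refer to a centroid that does not exist")
    total = float(((pts - pts.mean(axis=0)) ** 2).sum())
    if total == 0.0:
        return 0.0
    within = float(((pts - centroids[labels]) ** 2).sum())
    return 1.0 - within / total


@dataclass
class StateClusterModel:
    """Two-stage k-means staging model.

    ``emg_centroids`` are the two 1-D centroids on the smoothed-log EMG axis
    (larger one maps to WAKE); ``sleep_dt_centroids`` the two centroids on the
    delta/theta axis fitted within the sleep cluster only (larger -> NREM).
    ``state_centroids`` are the per-state means in standardized 3-D feature
    space, used for out-of-sample nearest-centroid assignment.
    """

    emg_centroids: np.ndarray
    sleep_dt_centroids: np.ndarray
    state_centroids: np.ndarray  # 3 x 3, rows ordered (WAKE, NREM, REM)
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    state_order: tuple[str, ...] = STATES
    training_labels: np.ndarray | None = field(default=None, repr=False)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_sd


def _standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def fit_state_clusters(
    feats: FeatureSeries, seed: int = 0, restarts: int = DEFAULT_RESTARTS
) -> StateClusterModel:
    """Two-stage unsupervised staging of smoothed-log features.

    Stage 1 clusters the EMG r.m.s. values into two groups; the group with the
    higher centroid is Wake, the other sleep. Stage 2 clusters the delta/theta
    ratio of the sleep epochs into two groups; higher centroid -> NREM, lower
    -> REM. The per-state means in standardized 3-D space become the centroids
    used to score new data.
    """
    if feats.stage != "smoothed_log":
        raise ValueError("staging requires smoothed_log features")
    n = len(feats)
    if n < 30:
        raise DegenerateInputError(f"need >= 30 epochs to fit staging, got {n}")
    emg = feats.emg_rms
    if np.unique(emg).size < 2:
        raise DegenerateInputError("EMG axis has fewer than 2 distinct values")

    c1, lab1, _ = kmeans(emg, 2, seed=seed, restarts=restarts)
    wake_cluster = int(np.argmax(c1.ravel()))
    is_wake = lab1 == wake_cluster

    sleep_dt = feats.dt_ratio[~is_wake]
    if np.unique(sleep_dt).size < 2:
        raise CannotSplitSleepError(
            "sleep cluster has fewer than 2 distinct delta/theta values"
        )
    c2, lab2, _ = kmeans(sleep_dt, 2, seed=seed, restarts=restarts)
    nrem_cluster = int(np.argmax(c2.ravel()))

    labels = np.empty(n, dtype=np.int64)
    labels[is_wake] = WAKE
    sleep_labels = np.where(lab2 == nrem_cluster, NREM, REM)
    labels[~is_wake] = sleep_labels

    X = feats.as_matrix()
    mean, sd = _standardization(X)
    Z = (X - mean) / sd
    state_centroids = np.vstack(
        [
            Z[labels == s].mean(axis=0) if np.any(labels == s) else np.zeros(3)
            for s in (WAKE, NREM, REM)
        ]
    )
    return StateClusterModel(
        emg_centroids=np.sort(c1.ravel()),
        sleep_dt_centroids=np.sort(c2.ravel()),
        state_centroids=state_centroids,
        feature_mean=mean,
        feature_sd=sd,
        training_labels=labels,
    )


def assign_states(model: StateClusterModel, feats: FeatureSeries) -> Hypnogram:
    """Label each epoch by the nearest state centroid (standardized Euclidean).

    Ties resolve to the state earliest in (WAKE, NREM, REM).
    """
    Z = model.standardize(feats.as_matrix())
    d2 = ((Z[:, None, :] - model.state_centroids[None, :, :]) ** 2).sum(axis=2)
    return Hypnogram(labels=np.argmin(d2, axis=1), epoch_s=feats.epoch_s)


@dataclass
class ObservationCodebook:
    """M-centroid vector quantizer of the standardized feature space."""

    centroids: np.ndarray  # M x 3, standardized coordinates
    M: int
    vc: float
    vc_threshold: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    threshold_reached: bool = True

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_sd


def fit_codebook(
    feats: FeatureSeries,
    kmin: int = 3,
    kmax: int = 15,
    vc_threshold: float = 0.90,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> ObservationCodebook:
    """Select the smallest codebook size M in [kmin, kmax] whose explained
    variance reaches ``vc_threshold``.

    If no M reaches the threshold the codebook uses ``kmax`` and is flagged
    (``threshold_reached=False``).
    """
    if feats.stage != "smoothed_log":
        raise ValueError("codebook requires smoothed_log features")
    X = feats.as_matrix()
    mean, sd = _standardization(X)
    Z = (X - mean) / sd
    n_distinct = np.unique(Z, axis=0).shape[0]
    if n_distinct < kmin:
        raise DegenerateInputError(
            f"{n_distinct} distinct points cannot form {kmin} clusters"
        )
    kmax_eff = min(kmax, n_distinct)
    best: tuple[np.ndarray, int, float] | None = None
    for M in range(kmin, kmax_eff + 1):
        centroids, labels, _ = kmeans(Z, M, seed=seed, restarts=restarts)
        vc = variance_criterion(Z, labels, centroids)
        best = (centroids, M, vc)
        if vc >= vc_threshold:
            return ObservationCodebook(
                centroids=centroids,
                M=M,
                vc=vc,
                vc_threshold=vc_threshold,
                feature_mean=mean,
                feature_sd=sd,
                threshold_reached=True,
            )
    assert best is not None
    centroids, M, vc = best
    return ObservationCodebook(
        centroids=centroids,
        M=M,
        vc=vc,
        vc_threshold=vc_threshold,
        feature_mean=mean,
        feature_sd=sd,
        threshold_reached=False,
    )


def quantize(codebook: ObservationCodebook, feats: FeatureSeries) -> np.ndarray:
    """Map each epoch to the index of its nearest codebook centroid.

    Ties resolve to the lowest index. Returns an int array of symbols in
    ``[0, M-1]`` with one entry per epoch.
    """
    Z = codebook.standardize(feats.as_matrix())
    d2 = ((Z[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.int64)
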