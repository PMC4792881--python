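"""Sleep-architecture metrics and scorer-agreement statistics.

The quantities of interest in sleep research are, per vigilance state: the
percentage of recording time spent in the state, the number of bouts
(maximal runs of consecutive epochs in the state), and the mean bout
duration. Agreement between two scorers of the same recording is summarized
by a 3 x 3 confusion matrix with one-vs-rest sensitivity/specificity and
overall percent agreement.

``compare_scorers`` builds the cohort-level comparison used to contrast a
static (per-epoch nearest-centroid) scorer with a dynamic (HMM/Viterbi)
scorer: per-subject metric errors, Wilcoxon signed-rank tests of those
errors across subjects, and Spearman correlations between predicted and
reference metric values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._types import N_STATES, STATES, AlignmentError, Hypnogram

__all__ = [
    "Bout",
    "SleepMetrics",
    "AgreementReport",
    "bouts",
    "sleep_metrics",
    "agreement",
    "compare_scorers",
]

METRIC_NAMES = ("percent_time", "n_bouts", "mean_bout_s")


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive epochs in one state."""

    state: int
    start_epoch: int
    length_epochs: int

    @property
    def state_name(self) -> str:
        return STATES[self.state]


@dataclass
class SleepMetrics:
    """Per-state percent time, bout count and mean bout duration (seconds).

    ``mean_bout_s`` is NaN for a state with no bouts (distinguishing "absent"
    from "zero-length").
    """

    percent_time: np.ndarray  # length 3, sums to 100
    n_bouts: np.ndarray  # length 3, ints
    mean_bout_s: np.ndarray  # length 3, NaN where n_bouts == 0
    epoch_s: float
    n_epochs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": STATES,
                "percent_time": self.percent_time,
                "n_bouts": self.n_bouts,
                "mean_bout_s": self.mean_bout_s,
            }
        )


@dataclass
class AgreementReport:
    """Confusion matrix (reference rows x predicted columns) and summary rates."""

    confusion: np.ndarray  # 3 x 3 counts
    overall: float  # percent
    sensitivity: np.ndarray  # per state, percent
    specificity: np.ndarray  # per state, percent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": STATES,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "overall": self.overall,
            }
        )


def bouts(h: Hypnogram) -> list[Bout]:
    """Run-length encode a hypnogram into its maximal same-state runs."""
    labels = h.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [
        Bout(state=int(labels[s]), start_epoch=int(s), length_epochs=int(e - s))
        for s, e in zip(starts, ends)
    ]


def sleep_metrics(h: Hypnogram) -> SleepMetrics:
    """Percent time, bout number and mean bout duration per state."""
    runs = bouts(h)
    n = len(h)
    percent = np.array([np.sum(h.labels == s) for s in range(N_STATES)]) * 100.0 / n
    n_bouts = np.zeros(N_STATES, dtype=np.int64)
    total_len = np.zeros(N_STATES)
    for b in runs:
        n_bouts[b.state] += 1
        total_len[b.state] += b.length_epochs
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_bout_s = np.where(
            n_bouts > 0, total_len * h.epoch_s / np.maximum(n_bouts, 1), np.nan
        )
    return SleepMetrics(
        percent_time=percent,
        n_bouts=n_bouts,
        mean_bout_s=mean_bout_s,
        epoch_s=h.epoch_s,
        n_epochs=n,
    )


def agreement(ref: Hypnogram, pred: Hypnogram) -> AgreementReport:
    """Epoch-by-epoch agreement of a predicted hypnogram against a reference.

    Sensitivity and specificity are one-vs-rest per state; overall agreement
    is the percentage of epochs on the confusion-matrix diagonal.
    """
    if len(ref) != len(pred) or ref.epoch_s != pred.epoch_s:
        raise AlignmentError(
            "reference and prediction must have equal length and epoch duration"
        )
    conf = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    np.add.at(conf, (ref.labels, pred.labels), 1)
    total = conf.sum()
    overall = 100.0 * np.trace(conf) / total
    sens = np.empty(N_STATES)
    spec = np.empty(N_STATES)
    for s in range(N_STATES):
        tp = conf[s, s]
        fn = conf[s].sum() - tp
        fp = conf[:, s].sum() - tp
        tn = total - tp - fn - fp
        sens[s] = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
        spec[s] = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
    return AgreementReport(
        confusion=conf, overall=float(overall), sensitivity=sens, specificity=spec
    )


def _metric_table(h: Hypnogram) -> np.ndarray:
    m = sleep_metrics(h)
    return np.vstack([m.percent_time, m.n_bouts.astype(float), m.mean_bout_s])


def compare_scorers(
    ref: Sequence[Hypnogram],
    pred_km: Sequence[Hypnogram],
    pred_hmm: Sequence[Hypnogram],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort comparison of two automatic scorers against a reference scorer.

    Parameters are per-subject hypnogram sequences (aligned within subject).
    Returns ``(errors, tests)``:

    * ``errors`` — one row per (subject, scorer, state) with the three metric
      values and signed errors (predicted − reference).
    * ``tests`` — one row per (scorer, state, metric) with the across-subject
      Wilcoxon signed-rank statistic and p-value on the paired errors, and
      the Spearman rank correlation between predicted and reference values.
      Wilcoxon uses the exact distribution where scipy's rules allow (small
      samples without ties), normal approximation otherwise; Spearman uses
      mid-ranks for ties. Requires at least 2 subjects.
    """
    n_subj = len(ref)
    if not (len(pred_km) == len(pred_hmm) == n_subj):
        raise AlignmentError("per-scorer hypnogram lists must have equal length")
    if n_subj < 2:
        raise ValueError("need at least 2 subjects for cohort statistics")

    rows = []
    # values[scorer][metric, state, subject]
    values = {
        name: np.empty((3, N_STATES, n_subj))
        for name in ("reference", "kmeans", "hmm")
    }
    for i, (r, km, hm) in enumerate(zip(ref, pred_km, pred_hmm)):
        if len(km) != len(r) or len(hm) != len(r):
            raise AlignmentError(f"subject {i}: hypnograms are not aligned")
        tabs = {"reference": _metric_table(r), "kmeans": _metric_table(km),
                "hmm": _metric_table(hm)}
        for name, tab in tabs.items():
            values[name][:, :, i] = tab
        for scorer in ("kmeans", "hmm"):
            for s in range(N_STATES):
                for j, metric in enumerate(METRIC_NAMES):
                    rows.append(
                        {
                            "subject": i,
                            "scorer": scorer,
                            "state": STATES[s],
                            "metric": metric,
                            "reference": tabs["reference"][j, s],
                            "predicted": tabs[scorer][j, s],
                            "error": tabs[scorer][j, s] - tabs["reference"][j, s],
                        }
                    )
    errors = pd.DataFrame(rows)

    test_rows = []
    for scorer in ("kmeans", "hmm"):
        for s in range(N_STATES):
            for j, metric in enumerate(METRIC_NAMES):
                refv = values["reference"][j, s]
                predv = values[scorer][j, s]
                ok = np.isfinite(refv) & np.isfinite(predv)
                d = predv[ok] - refv[ok]
                if d.size >= 2 and np.any(d != 0):
                    w_stat, w_p = stats.wilcoxon(d)
                elif d.size >= 2:
                    w_stat, w_p = 0.0, 1.0
                else:
                    w_stat, w_p = np.nan, np.nan
                if d.size >= 2 and np.std(refv[ok]) > 0 and np.std(predv[ok]) > 0:
                    rho = stats.spearmanr(refv[ok], predv[ok]).statistic
                elif d.size >= 2 and np.allclose(d, 0):
                    rho = 1.0
                else:
                    rho = np.nan
                test_rows.append(
                    {
                        "scorer": scorer,
                        "state": STATES[s],
                        "metric": metric,
                        "n": int(ok.sum()),
                        "wilcoxon_stat": w_stat,
                        "wilcoxon_p": w_p,
                        "spearman_rho": rho,
                    }
                )
    return errors, pd.DataFrame(test_rows)
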