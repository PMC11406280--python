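"""Per-species / per-observation accuracy metric suite and trivial baselines.

Three metric families:

* **binary** (at a stated threshold, default 0.5): precision, recall, F1
  per species and per observation, plus presence accuracy — the fraction
  of true (observation, present-species) pairs predicted present;
* **discrimination**: AUC_ROC (Mann-Whitney tie convention) and AUC_PRC
  (step-wise average-precision construction), per species;
* **ranking**: Top-K accuracy per observation and per species, and mean
  average precision.

Aggregates report medians with interquartile ranges, matching how
heavily-skewed per-species score distributions are usually summarized.
Species for which a metric is undefined (single-class columns) are
excluded from aggregation.  Two data-independent baselines — i.i.d.
standard-normal scores through a logistic, and constant per-species
training-frequency scores — calibrate the floor of every metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from . import nn

DEFAULT_TOPK = (1, 5, 30, 100)


@dataclass
class ScoreMatrix:
    """Aligned scores and binary targets for N observations x S species."""

    scores: np.ndarray
    targets: np.ndarray
    species_names: list[str] = field(default_factory=list)
    anchor_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.targets = np.asarray(self.targets).astype(bool)
        if self.scores.shape != self.targets.shape:
            raise ValueError("scores and targets shapes differ")
        if not self.species_names:
            self.species_names = [f"s{i}" for i in range(self.scores.shape[1])]
        if not self.anchor_ids:
            self.anchor_ids = [f"a{i}" for i in range(self.scores.shape[0])]

    @property
    def n_obs(self) -> int:
        return self.scores.shape[0]

    @property
    def n_species(self) -> int:
        return self.scores.shape[1]


@dataclass
class MetricReport:
    """Per-species table plus aggregate scalars at a stated threshold."""

    per_species: pd.DataFrame
    aggregates: dict[str, float]
    threshold: float


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney statistic.

    The probability that a random positive outscores a random negative,
    ties counting one half.  Returns ``nan`` (undefined sentinel) when
    either class is absent.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def auc_prc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision steps).

    Returns ``nan`` when there is no positive.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.sum() == 0:
        return float("nan")
    return float(average_precision_score(labels, np.asarray(scores, float)))


def _prf(tp: np.ndarray, pred_pos: np.ndarray, actual_pos: np.ndarray):
    """Vectorized precision/recall/F1 with the 0-when-undefined convention."""
    precision = np.divide(tp, pred_pos, out=np.zeros_like(tp, dtype=float),
                          where=pred_pos > 0)
    recall = np.divide(tp, actual_pos, out=np.zeros_like(tp, dtype=float),
                       where=actual_pos > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom,
                   out=np.zeros_like(denom), where=denom > 0)
    return precision, recall, f1


def threshold_metrics(sm: ScoreMatrix, threshold: float = 0.5) -> dict:
    """Binary classification metrics at ``score > threshold``.

    Per-species metrics run down columns, per-observation metrics across
    rows; presence accuracy is the fraction of all true
    (observation, species) presence pairs predicted present.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    pred = sm.scores > threshold
    y = sm.targets
    tp_s = (pred & y).sum(axis=0).astype(float)
    p_s, r_s, f_s = _prf(tp_s, pred.sum(axis=0).astype(float),
                         y.sum(axis=0).astype(float))
    tp_o = (pred & y).sum(axis=1).astype(float)
    p_o, r_o, f_o = _prf(tp_o, pred.sum(axis=1).astype(float),
                         y.sum(axis=1).astype(float))
    total_pos = int(y.sum())
    presence_acc = float((pred & y).sum() / total_pos) if total_pos else 0.0
    return {
        "species_precision": p_s, "species_recall": r_s, "species_f1": f_s,
        "obs_precision": p_o, "obs_recall": r_o, "obs_f1": f_o,
        "presence_accuracy": presence_acc,
    }


def _top_k_membership(scores: np.ndarray, k: int) -> np.ndarray:
    """Boolean (N, S) mask of each row's K best scores.

    Score ties are broken by ascending species index for reproducibility.
    """
    n, s = scores.shape
    order = np.lexsort((np.broadcast_to(np.arange(s), (n, s)), -scores), axis=1)
    mask = np.zeros((n, s), dtype=bool)
    np.put_along_axis(mask, order[:, :k], True, axis=1)
    return mask


def topk_accuracy(sm: ScoreMatrix, k: int) -> dict:
    """Top-K accuracy per observation (mean) and per species (median).

    Per observation: the fraction of the row's true species ranked within
    its K best scores.  Per species: over observations containing the
    species, the fraction where it makes the top K.
    """
    if k > sm.n_species:
        raise ValueError("K cannot exceed the number of species")
    top = _top_k_membership(sm.scores, k)
    y = sm.targets
    hits = (top & y).sum(axis=1).astype(float)
    row_pos = y.sum(axis=1).astype(float)
    obs_fraction = np.divide(hits, row_pos, out=np.full(sm.n_obs, np.nan),
                             where=row_pos > 0)
    support = y.sum(axis=0).astype(float)
    sp_rate = np.divide((top & y).sum(axis=0), support,
                        out=np.full(sm.n_species, np.nan), where=support > 0)
    return {
        "obs_fractions": obs_fraction,
        "obs_mean": float(np.nanmean(obs_fraction)),
        "species_rates": sp_rate,
        "species_median": float(np.nanmedian(sp_rate)),
    }


def mean_average_precision(sm: ScoreMatrix) -> float:
    """Mean over species (with >= 1 positive) of observation-wise AP."""
    values = [auc_prc(sm.scores[:, s], sm.targets[:, s])
              for s in range(sm.n_species)]
    values = [v for v in values if not np.isnan(v)]
    if not values:
        raise ValueError("no species has a positive observation")
    return float(np.mean(values))


def _quartiles(values: np.ndarray):
    v = values[~np.isnan(values)]
    if v.size == 0:
        return float("nan"), float("nan"), float("nan")
    return (float(np.median(v)), float(np.quantile(v, 0.25)),
            float(np.quantile(v, 0.75)))


def metric_report(sm: ScoreMatrix, threshold: float = 0.5,
                  topk: Sequence[int] = DEFAULT_TOPK) -> MetricReport:
    """The full metric suite on one score matrix."""
    topk = [k for k in topk if k <= sm.n_species]
    per_roc = np.array([auc_roc(sm.scores[:, s], sm.targets[:, s])
                        for s in range(sm.n_species)])
    per_prc = np.array([auc_prc(sm.scores[:, s], sm.targets[:, s])
                        for s in range(sm.n_species)])
    binary = threshold_metrics(sm, threshold)
    table = pd.DataFrame({
        "species": sm.species_names,
        "support": sm.targets.sum(axis=0),
        "auc_roc": per_roc,
        "auc_prc": per_prc,
        "precision": binary["species_precision"],
        "recall": binary["species_recall"],
        "f1": binary["species_f1"],
    })
    agg: dict[str, float] = {"presence_accuracy": binary["presence_accuracy"],
                             "mean_average_precision": mean_average_precision(sm)}
    for name, vals in (("auc_roc", per_roc), ("auc_prc", per_prc),
                       ("precision", binary["species_precision"]),
                       ("recall", binary["species_recall"]),
                       ("f1", binary["species_f1"])):
        med, q1, q3 = _quartiles(np.asarray(vals, dtype=float))
        agg[f"{name}_spp_median"] = med
        agg[f"{name}_spp_q1"], agg[f"{name}_spp_q3"] = q1, q3
    for name, vals in (("precision", binary["obs_precision"]),
                       ("recall", binary["obs_recall"]),
                       ("f1", binary["obs_f1"])):
        med, q1, q3 = _quartiles(np.asarray(vals, dtype=float))
        agg[f"{name}_obs_median"] = med
    for k in topk:
        tk = topk_accuracy(sm, k)
        table[f"top{k}"] = tk["species_rates"]
        agg[f"top{k}_obs_mean"] = tk["obs_mean"]
        agg[f"top{k}_spp_median"] = tk["species_median"]
    return MetricReport(table, agg, threshold)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def random_baseline_report(targets: np.ndarray, trials: int = 10,
                           seed: int = 0, threshold: float = 0.5,
                           topk: Sequence[int] = DEFAULT_TOPK) -> MetricReport:
    """Metric suite under i.i.d. standard-normal scores, averaged over trials.

    Scores are drawn from N(0, 1) and mapped through the logistic function;
    the metric suite is computed per trial and every aggregate (and the
    per-species table) is averaged across the ``trials`` seeded draws.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    targets = np.asarray(targets).astype(bool)
    reports = []
    for _ in range(trials):
        scores = nn.sigmoid(rng.standard_normal(targets.shape))
        reports.append(metric_report(ScoreMatrix(scores, targets),
                                     threshold, topk))
    agg = {k: float(np.mean([r.aggregates[k] for r in reports]))
           for k in reports[0].aggregates}
    numeric = reports[0].per_species.select_dtypes("number").columns
    table = reports[0].per_species.copy()
    table[numeric] = np.mean([r.per_species[numeric].to_numpy()
                              for r in reports], axis=0)
    return MetricReport(table, agg, threshold)


def frequency_baseline_scores(train_counts: np.ndarray,
                              n_obs: int,
                              targets: np.ndarray | None = None,
                              low: float = 0.001, high: float = 1.0
                              ) -> ScoreMatrix:
    """Constant per-species scores from training frequencies.

    Relative training frequencies are linearly rescaled so the rarest
    species maps to ``low`` (0.001) and the commonest to ``high`` (1.0);
    the same score row is repeated for every evaluation observation.
    """
    counts = np.asarray(train_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("training frequencies are all zero")
    freq = counts / counts.sum()
    lo, hi = freq.min(), freq.max()
    if hi == lo:
        row = np.full_like(freq, high)
    else:
        row = low + (freq - lo) * (high - low) / (hi - lo)
    scores = np.tile(row, (n_obs, 1))
    if targets is None:
        targets = np.zeros_like(scores, dtype=bool)
    return ScoreMatrix(scores, targets)
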