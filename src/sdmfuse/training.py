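"""Losses, sampling-effort completeness, and the training loop.

The centerpiece is the **sampling-aware binary cross-entropy**.  Citizen
science never records the full species list at a location, so treating
unrecorded species as confident absences both swamps the few positives and
punishes the model hardest exactly where sampling is thinnest.  The loss
fixes both problems at once: within each observation the present-species
and absent-species terms are mean-balanced, and the absent term is scaled
by an estimated per-location completeness c_i in (0, 1],

    L = (1/N) sum_i [ -(1/|P_i|) sum_{s in P_i} log p_is
                      - c_i (1/|A_i|) sum_{s in A_i} log(1 - p_is) ],

with p = sigmoid(logits), P_i / A_i the present / absent species of row i.
Completeness is estimated as the local species richness relative to a high
quantile of richness across all anchors.

Training is seeded mini-batch Adam; after each epoch the mean per-species
AUC_ROC on a monitoring split is computed and the best epoch's weights are
kept (early stopping).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .labeling import LabelSet
from .model import ModelOutputs, _BaseModel
from .partitioning import SplitSpec
from .sampling import SampleRecord

log = logging.getLogger(__name__)

LOSSES = ("sampling_aware_bce", "bce", "ce")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  Defaults: 13 epochs of Adam."""

    epochs: int = 13
    learning_rate: float = 1e-3
    batch_size: int = 64
    loss_name: str = "sampling_aware_bce"
    rank_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.loss_name not in LOSSES:
            raise ValueError(f"loss_name must be one of {LOSSES}")


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_auc: list[float] = field(default_factory=list)
    selected_epoch: int = 0


def learning_rate_sweep(low: float = 5e-6, high: float = 1e-1) -> list[float]:
    """Candidate learning rates in multiplicative half-decade steps."""
    rates = []
    lr = low
    while lr <= high * (1 + 1e-9):
        rates.append(float(lr))
        lr *= 10 ** 0.5
    return rates


# ---------------------------------------------------------------------------
# completeness estimation
# ---------------------------------------------------------------------------

def estimate_location_completeness(labels: Sequence[LabelSet],
                                   radius_m: float = 256.0,
                                   reference_quantile: float = 0.95
                                   ) -> dict[str, float]:
    """Per-anchor sampling completeness c_i = min(1, n_i / n_ref).

    n_i counts the distinct species recorded within ``radius_m`` of anchor
    i, and n_ref is the ``reference_quantile`` of {n_i} over all anchors —
    a proxy for how thoroughly surveyed a well-sampled neighborhood is.
    """
    if not labels:
        return {}
    xy = np.array([(ls.x, ls.y) for ls in labels], dtype=float)
    own = [ls.own_species_idx for ls in labels]
    tree = cKDTree(xy)
    neighborhoods = tree.query_ball_point(xy, radius_m)
    n = np.array([len({own[j] for j in nbrs}) for nbrs in neighborhoods],
                 dtype=float)
    n_ref = float(np.quantile(n, reference_quantile))
    if n_ref <= 0:
        raise ValueError("reference richness quantile is zero")
    c = np.minimum(1.0, n / n_ref)
    return {ls.anchor_id: float(max(ci, 1e-12))
            for ls, ci in zip(labels, c)}


# ---------------------------------------------------------------------------
# losses (each returns the scalar; with return_grad=True also d loss / d logits)
# ---------------------------------------------------------------------------

def sampling_aware_bce(logits: np.ndarray, targets: np.ndarray,
                       completeness: np.ndarray, return_grad: bool = False):
    """Mean-balanced, completeness-weighted binary cross-entropy.

    Each row must contain at least one positive.  A row with no negatives
    contributes only its positive term.
    """
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets)
    c = np.asarray(completeness, dtype=float)
    n, _ = logits.shape
    pos = targets.astype(bool)
    n_pos = pos.sum(axis=1)
    n_neg = (~pos).sum(axis=1)
    if np.any(n_pos == 0):
        raise ValueError("every row needs at least one present species")
    pos_term = np.where(pos, nn.softplus(-logits), 0.0).sum(axis=1) / n_pos
    neg_sum = np.where(~pos, nn.softplus(logits), 0.0).sum(axis=1)
    neg_term = c * np.divide(neg_sum, n_neg, out=np.zeros(n), where=n_neg > 0)
    loss = float(np.mean(pos_term + neg_term))
    if not return_grad:
        return loss
    p = nn.sigmoid(logits)
    grad = np.where(pos, -(1.0 - p) / n_pos[:, None],
                    (c / np.maximum(n_neg, 1))[:, None] * p) / n
    return loss, grad


def multilabel_bce(logits: np.ndarray, targets: np.ndarray,
                   return_grad: bool = False):
    """Standard element-wise binary cross-entropy, mean over all entries."""
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    loss = float(np.mean(nn.softplus(logits) - logits * y))
    if not return_grad:
        return loss
    return loss, (nn.sigmoid(logits) - y) / logits.size


def single_label_ce(logits: np.ndarray, targets: np.ndarray,
                    rng: np.random.Generator, return_grad: bool = False):
    """Softmax cross-entropy with one uniformly sampled positive per row.

    Reproduces the single-label training style of earlier remote-sensing
    classifiers on multilabel data.
    """
    logits = np.asarray(logits, dtype=float)
    n, s = logits.shape
    chosen = np.empty(n, dtype=int)
    for i in range(n):
        positives = np.flatnonzero(targets[i])
        if positives.size == 0:
            raise ValueError("every row needs at least one present species")
        chosen[i] = rng.choice(positives)
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), chosen]))
    if not return_grad:
        return loss
    softmax = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    grad = softmax
    grad[np.arange(n), chosen] -= 1.0
    return loss, grad / n


def multirank_loss(outputs: ModelOutputs, targets_by_rank,
                   completeness: np.ndarray,
                   rank_weights=(1.0, 1.0, 1.0),
                   loss_name: str = "sampling_aware_bce",
                   rng: np.random.Generator | None = None):
    """Weighted sum of the configured loss at species, genus, family ranks.

    Returns ``(scalar, (d_species, d_genus, d_family))``.
    """
    logits_by_rank = (outputs.species_logits, outputs.genus_logits,
                      outputs.family_logits)
    total = 0.0
    grads = []
    for w, logits, targets in zip(rank_weights, logits_by_rank, targets_by_rank):
        if loss_name == "sampling_aware_bce":
            value, grad = sampling_aware_bce(logits, targets, completeness,
                                             return_grad=True)
        elif loss_name == "bce":
            value, grad = multilabel_bce(logits, targets, return_grad=True)
        elif loss_name == "ce":
            if rng is None:
                raise ValueError("ce loss needs an rng for positive sampling")
            value, grad = single_label_ce(logits, targets, rng, return_grad=True)
        else:
            raise ValueError(f"unknown loss {loss_name!r}")
        total += w * value
        grads.append(w * grad)
    return total, tuple(grads)


# ---------------------------------------------------------------------------
# target assembly and the loop
# ---------------------------------------------------------------------------

def target_matrices(samples: Sequence[SampleRecord], n_species: int,
                    n_genera: int, n_families: int):
    """Dense binary target matrices at the three ranks."""
    n = len(samples)
    ys = np.zeros((n, n_species), dtype=bool)
    yg = np.zeros((n, n_genera), dtype=bool)
    yf = np.zeros((n, n_families), dtype=bool)
    for i, rec in enumerate(samples):
        ys[i, sorted(rec.labels.species_idx)] = True
        yg[i, sorted(rec.labels.genus_idx)] = True
        yf[i, sorted(rec.labels.family_idx)] = True
    return ys, yg, yf


def _mean_species_auc(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean per-species AUC_ROC over species with both classes present."""
    from .evaluation import auc_roc
    values = [auc_roc(probs[:, s], targets[:, s])
              for s in range(targets.shape[1])]
    values = [v for v in values if not np.isnan(v)]
    return float(np.mean(values)) if values else float("nan")


def train_model(net: _BaseModel, samples: Sequence[SampleRecord],
                split: SplitSpec, config: TrainConfig):
    """Seeded mini-batch training with per-epoch AUC early stopping.

    The monitoring split is the test side of ``split`` (falls back to the
    training data when the test side is empty).  Returns the model loaded
    with the best epoch's weights and the full :class:`TrainHistory`.
    """
    cfg = net.config
    by_id = {s.anchor_id: s for s in samples}
    train_recs = [by_id[a] for a in sorted(split.train_ids) if a in by_id]
    monitor_recs = [by_id[a] for a in sorted(split.test_ids) if a in by_id]
    if not train_recs:
        raise ValueError("split train set is empty")
    if not monitor_recs:
        monitor_recs = train_recs

    def arrays(recs):
        images = (np.stack([r.image for r in recs]).astype(float)
                  if net.inputs != "climate" else None)
        climate = np.stack([r.climate for r in recs])
        ys, yg, yf = target_matrices(recs, cfg.n_species, cfg.n_genera,
                                     cfg.n_families)
        c = np.array([r.completeness for r in recs])
        return images, climate, ys, yg, yf, c

    tr_img, tr_clim, tr_ys, tr_yg, tr_yf, tr_c = arrays(train_recs)
    mon_img, mon_clim, mon_ys, *_ = arrays(monitor_recs)

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(net.params(), config.learning_rate)
    history = TrainHistory()
    best_auc, best_state = -np.inf, net.state()
    n = len(train_recs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            outputs = net.forward(None if tr_img is None else tr_img[idx],
                                  tr_clim[idx], train=True)
            loss, grads = multirank_loss(
                outputs, (tr_ys[idx], tr_yg[idx], tr_yf[idx]), tr_c[idx],
                config.rank_weights, config.loss_name, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{loss}; try a lower learning rate")
            optimizer.zero_grad()
            net.backward(*grads)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        history.epoch_loss.append(epoch_loss / max(n_batches, 1))

        from .model import predict_probabilities
        probs = predict_probabilities(net, (mon_img, mon_clim))
        auc = _mean_species_auc(probs, mon_ys)
        history.epoch_auc.append(auc)
        if not np.isnan(auc) and auc > best_auc:
            best_auc = auc
            best_state = net.state()
            history.selected_epoch = epoch
        elif np.isinf(best_auc):
            # AUC undefined on the monitoring split so far (single-class
            # species columns): fall back to the latest weights
            best_state = net.state()
            history.selected_epoch = epoch
        log.info("epoch %d: loss %.4f, monitor AUC %.4f", epoch,
                 history.epoch_loss[-1], auc)
    net.load_state(best_state)
    return net, history
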