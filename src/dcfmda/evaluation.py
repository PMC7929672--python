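"""Cross-validated evaluation of association predictors.

Implements the link-prediction protocol: known associations are the
positives, unobserved pairs are sampled as negatives at a fixed ratio,
the joint sample set is split into k near-equal random folds, and each
fold is scored by a model trained on the other k-1.  Metrics are ROC/AUC,
precision-recall, and F1 at top-K cutoffs, reported both pooled over all
test folds and as a per-fold mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .containers import AssociationMatrix, SimilarityMatrix
from .model import (
    ModelConfig,
    PredictionMatrix,
    sample_negatives,
    score_pairs,
    train_ensemble,
)
from .similarity import SimilarityBundle

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "RankedCandidates",
    "kfold_split",
    "roc_auc",
    "pr_curve",
    "f1_topk",
    "cross_validate",
    "rank_candidates",
]

DEFAULT_TOPK_GRID = tuple(range(100, 1001, 100))


@dataclass
class FoldAssignment:
    """Fold index (0-based) per sample; folds partition the sample set."""

    fold_of: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def kfold_split(n_samples: int, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition into k folds whose sizes differ by <= 1."""
    if k < 2:
        raise ValueError("number of folds must be >= 2")
    if k > n_samples:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    fold_of = np.empty(n_samples, dtype=np.int64)
    # first (n mod k) folds get one extra sample
    sizes = np.full(k, n_samples // k)
    sizes[: n_samples % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        fold_of[order[start:start + size]] = fold
        start += size
    return FoldAssignment(fold_of, k)


def roc_auc(scores, labels):
    """ROC curve points and AUC.

    The AUC from a trapezoidal sweep over the ROC step points equals the
    rank statistic: the probability that a random positive outscores a
    random negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skm.auc(fpr, tpr))


def pr_curve(scores, labels):
    """Precision-recall points, ordered by increasing recall, ending at
    recall 1 (the all-inclusive threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("PR curve requires at least one positive")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    # reverse into increasing recall; at full recall keep only the
    # tightest threshold (dominated looser thresholds add no information)
    pts = list(zip(recall.tolist(), precision.tolist()))[::-1]
    full = [p for r, p in pts if r == 1.0]
    if full:
        best = max(full)
        pts = [(r, p) for r, p in pts if r < 1.0 or p == best]
    return pts


def _topk_order(scores: np.ndarray, tiebreak=None) -> np.ndarray:
    """Descending-score order; ties broken by ascending tiebreak key."""
    if tiebreak is None:
        tiebreak = np.arange(scores.size)
    order = np.lexsort((np.asarray(tiebreak), -np.asarray(scores, dtype=float)))
    return order


def f1_topk(scores, labels, k: int, tiebreak=None) -> float:
    """F1 when the k highest-scoring samples are called positive.

    Ties at the k-th score are broken deterministically by the
    ``tiebreak`` key (position order by default).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > scores.size:
        raise ValueError("k exceeds number of samples")
    order = _topk_order(scores, tiebreak)
    called = np.zeros(scores.size, dtype=bool)
    called[order[:k]] = True
    tp = int(np.sum(called & (labels == 1)))
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or tp == 0:
        return 0.0
    precision = tp / k
    recall = tp / n_pos
    return float(2 * precision * recall / (precision + recall))


@dataclass
class EvaluationReport:
    """Pooled and per-fold metrics of one cross-validation run."""

    config: dict
    fold_auc: list[float]
    mean_auc: float
    sd_auc: float
    pooled_auc: float
    pooled_roc: list[tuple[float, float]]
    pooled_pr: list[tuple[float, float]]
    pooled_aupr: float
    f1_at_k: dict[int, float]
    fold_mean_f1_at_k: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "fold_auc": [round(a, 12) for a in self.fold_auc],
            "mean_auc": round(self.mean_auc, 12),
            "sd_auc": round(self.sd_auc, 12),
            "pooled_auc": round(self.pooled_auc, 12),
            "pooled_aupr": round(self.pooled_aupr, 12),
            "f1_at_k": {str(k): round(v, 12) for k, v in self.f1_at_k.items()},
            "fold_mean_f1_at_k": {
                str(k): round(v, 12) for k, v in self.fold_mean_f1_at_k.items()
            },
        }

    def to_json(self) -> str:
        """Deterministic serialisation (sorted keys, fixed rounding)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def cross_validate(
    assoc: AssociationMatrix,
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
    cfg: ModelConfig,
    k: int = 10,
    bundle: SimilarityBundle | None = None,
    topk_grid=None,
    log=None,
) -> EvaluationReport:
    """k-fold cross-validation of the fused predictor.

    Negatives are sampled once, before fold splitting, so positive and
    negative samples are partitioned jointly.  With
    ``cfg.gip_mode == "train_only"`` and a similarity ``bundle`` given,
    the Gaussian-kernel similarities (and the integrated matrices'
    fallback entries) are recomputed per fold from the training
    associations only, avoiding test leakage; ``"full_matrix"`` scores
    every fold against the similarities computed from the full matrix.
    """
    if cfg.gip_mode == "train_only" and bundle is None:
        logging.getLogger("dcfmda").info(
            "gip_mode=train_only but no similarity bundle supplied; "
            "kernels cannot be recomputed per fold and the full-matrix "
            "similarities will be used as-is"
        )
    samples = sample_negatives(
        assoc, assoc.positive_pairs(), cfg.negative_ratio, cfg.rng_seed
    )
    folds = kfold_split(samples.shape[0], k, cfg.rng_seed)
    if topk_grid is None:
        topk_grid = DEFAULT_TOPK_GRID

    pooled_scores = np.empty(samples.shape[0])
    fold_aucs = []
    fold_f1: dict[int, list[float]] = {}
    for fold in range(k):
        tr_idx = folds.train_indices(fold)
        te_idx = folds.test_indices(fold)
        tr, te = samples[tr_idx], samples[te_idx]
        held_out_pos = [(i, j) for i, j, y in te if y == 1]
        assoc_tr = assoc.mask_pairs(held_out_pos)
        if cfg.gip_mode == "train_only" and bundle is not None:
            fold_bundle = bundle.reintegrate(assoc_tr)
            ism_f, isd_f = fold_bundle.ism, fold_bundle.isd
        else:
            ism_f, isd_f = ism, isd
        members = train_ensemble(assoc_tr, ism_f, isd_f, cfg, samples=tr)
        yhat = score_pairs(members, te[:, 0], te[:, 1], ism_f, isd_f)
        pooled_scores[te_idx] = yhat
        _, auc = roc_auc(yhat, te[:, 2])
        fold_aucs.append(auc)
        for kk in topk_grid:
            if kk <= yhat.size:
                fold_f1.setdefault(kk, []).append(f1_topk(yhat, te[:, 2], kk))
        if log is not None:
            log(fold + 1, auc)

    labels = samples[:, 2]
    pooled_roc, pooled_auc = roc_auc(pooled_scores, labels)
    pooled_pr = pr_curve(pooled_scores, labels)
    rec = np.array([r for r, _ in pooled_pr])
    prec = np.array([p for _, p in pooled_pr])
    pooled_aupr = float(np.trapezoid(prec, rec))
    f1_at_k = {
        kk: f1_topk(pooled_scores, labels, kk)
        for kk in topk_grid
        if kk <= labels.size
    }
    return EvaluationReport(
        config={
            "folds": k,
            "negative_ratio": cfg.negative_ratio,
            "rng_seed": cfg.rng_seed,
            "gip_mode": cfg.gip_mode,
            "variant": cfg.variant,
            "embedding_dim": cfg.embedding_dim,
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "learning_rate": cfg.learning_rate,
            "n_models": cfg.n_models,
            "embedding_init": cfg.embedding_init,
        },
        fold_auc=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs)),
        pooled_auc=pooled_auc,
        pooled_roc=pooled_roc,
        pooled_pr=pooled_pr,
        pooled_aupr=pooled_aupr,
        f1_at_k=f1_at_k,
        fold_mean_f1_at_k={
            kk: float(np.mean(v)) for kk, v in sorted(fold_f1.items())
        },
    )


@dataclass
class RankedCandidates:
    """Top candidate miRNAs for one disease, unobserved in training."""

    disease: str
    ranking: list[tuple[str, float]]


def rank_candidates(
    pred: PredictionMatrix,
    assoc_train: AssociationMatrix,
    disease: str,
    top_k: int = 50,
) -> RankedCandidates:
    """Rank miRNAs unobserved for ``disease`` by descending score.

    Pairs observed in training are excluded; ties are broken by
    ascending miRNA identifier for determinism.
    """
    j = assoc_train.diseases.index(disease)
    candidates = [
        (pred.mirnas[i], float(pred.values[i, j]))
        for i in range(len(pred.mirnas))
        if assoc_train.values[i, j] == 0
    ]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return RankedCandidates(disease, candidates[:top_k])
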