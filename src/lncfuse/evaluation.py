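"""Cross-validated evaluation of target-block predictions.

The protocol treats every cell of the target block (lncRNA x cancer) as a
labelled example: observed associations are positives, unobserved cells are
negatives.  Cells are split into stratified folds; for each fold the test
positives are zeroed in the training copy of the target block, the fused
model is refit, and the reconstructed scores of the held-out cells are
evaluated.  The headline statistic is the mean of per-fold AUCs; a single
decision threshold is then chosen on the pooled out-of-fold scores by
maximizing the Matthews correlation coefficient (MCC).

Classification metrics follow the standard confusion-matrix definitions

    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    ACC  = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)

with MCC defined as 0 whenever a denominator factor vanishes, and AUC the
rank-based (Mann-Whitney) statistic with mid-rank tie handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .fusion import FitConfig, RankConfig, fit, reconstruct
from .relations import RelationGraph, RelationKey, RelationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricSet:
    """Threshold-dependent classification metrics plus AUC for one score set."""

    auc: float
    mcc: float
    acc: float
    precision: float
    sensitivity: float
    specificity: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "mcc": self.mcc,
            "acc": self.acc,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


@dataclass
class FoldAssignment:
    """Stratified fold ids over every target cell.

    ``pairs`` is an (n_cells, 2) integer array of (row, column) indices into
    the target block, ``labels`` the 0/1 cell values, ``fold_ids`` in 1..K.
    """

    pairs: np.ndarray
    labels: np.ndarray
    fold_ids: np.ndarray
    n_folds: int
    seed: int

    def test_cells(self, fold: int) -> np.ndarray:
        return self.pairs[self.fold_ids == fold]


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    mean_auc: float
    pooled: MetricSet
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    folds: FoldAssignment

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i + 1, **m.as_dict()) for i, m in enumerate(self.fold_metrics)]
        rows.append(dict(fold="pooled", **self.pooled.as_dict()))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scalar metrics


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie), via mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # mid-ranks on ties
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> MetricSet:
    """Metrics at a fixed cutoff; a cell is called positive iff score > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return MetricSet(
        auc=float("nan"),
        mcc=_mcc(tp, fp, fn, tn),
        acc=(tp + tn) / scores.size,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (fp + tn) if fp + tn else 0.0,
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def _mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def best_mcc_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, MetricSet]:
    """Exhaustive threshold scan maximizing MCC.

    Candidates are midpoints between consecutive distinct sorted scores plus
    a below-minimum and an above-maximum sentinel; ties in MCC resolve to the
    lowest threshold.  The returned MetricSet carries the AUC of the scores
    alongside the confusion metrics at the selected cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    best: MetricSet | None = None
    for thr in candidates:
        m = confusion_metrics(scores, labels, thr)
        if best is None or m.mcc > best.mcc + 1e-15:
            best = m
    assert best is not None
    best = replace(best, auc=auc(scores, labels))
    return best.threshold, best


# ---------------------------------------------------------------------------
# Cross-validation


def make_folds(graph: RelationGraph, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified partition of all target cells into ``n_folds`` folds.

    Within each label class, fold sizes differ by at most one; both classes
    must hold at least ``n_folds`` cells.  Deterministic given the seed.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    target = graph.target.values
    rows, cols = np.indices(target.shape)
    pairs = np.column_stack([rows.ravel(), cols.ravel()])
    labels = (target.ravel() != 0).astype(int)
    fold_ids = np.zeros(labels.size, dtype=int)
    rng = np.random.default_rng(seed)
    for label in (0, 1):
        idx = np.flatnonzero(labels == label)
        if idx.size < n_folds:
            raise ValueError(
                f"class {label} has only {idx.size} cells; use fewer than "
                f"{n_folds} folds"
            )
        perm = rng.permutation(idx)
        fold_ids[perm] = (np.arange(perm.size) % n_folds) + 1
    return FoldAssignment(pairs, labels, fold_ids, n_folds, seed)


def mask_fold(graph: RelationGraph, folds: FoldAssignment, fold: int) -> RelationGraph:
    """Training copy of the graph with this fold's positive cells zeroed.

    Negative test cells are already zero, so only test positives are masked;
    the target block therefore loses exactly the fold's positive count of
    nonzeros and no information about held-out associations leaks into
    training.
    """
    masked = graph.copy()
    tgt = masked.relations[graph.target_key].values
    sel = (folds.fold_ids == fold) & (folds.labels == 1)
    cells = folds.pairs[sel]
    tgt[cells[:, 0], cells[:, 1]] = 0.0
    return masked


def cross_validate(
    graph: RelationGraph,
    ranks: RankConfig,
    config: FitConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    folds: FoldAssignment | None = None,
) -> CVResult:
    """Stratified K-fold CV of the fused model on the target block.

    Per fold: mask test positives, refit, score the held-out cells from the
    reconstructed target block, and compute fold metrics at that fold's own
    best-MCC cutoff.  The summary is the mean fold AUC plus one pooled
    best-MCC threshold over all out-of-fold scores.
    """
    config = config or FitConfig()
    if folds is None:
        folds = make_folds(graph, n_folds, seed)
    pooled_scores = np.zeros(folds.labels.size)
    fold_metrics: list[MetricSet] = []
    for fold in range(1, folds.n_folds + 1):
        training = mask_fold(graph, folds, fold)
        try:
            model = fit(training, ranks, config)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"fit failed in fold {fold}: {exc}") from exc
        scores_block = reconstruct(model, graph.target_key)
        sel = folds.fold_ids == fold
        cells = folds.pairs[sel]
        fold_scores = scores_block[cells[:, 0], cells[:, 1]]
        pooled_scores[sel] = fold_scores
        _, metrics = best_mcc_threshold(fold_scores, folds.labels[sel])
        fold_metrics.append(metrics)
        logger.info("fold %d: auc=%.4f mcc=%.4f", fold, metrics.auc, metrics.mcc)
    mean_auc = float(np.mean([m.auc for m in fold_metrics]))
    _, pooled = best_mcc_threshold(pooled_scores, folds.labels)
    logger.info(
        "cv done: mean_auc=%.4f pooled_mcc=%.4f threshold=%.4f",
        mean_auc,
        pooled.mcc,
        pooled.threshold,
    )
    return CVResult(fold_metrics, mean_auc, pooled, pooled_scores, folds.labels, folds)


# ---------------------------------------------------------------------------
# Protocols: rank search and ablation


def rank_search(
    graph: RelationGraph,
    axes: list[str],
    grids: dict[str, list[int]],
    base_ranks: RankConfig,
    config: FitConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[RankConfig, pd.DataFrame]:
    """Coordinate search over per-type ranks, scored by mean CV AUC.

    Axes are optimized in order: the first axis scans its grid with all other
    ranks held at ``base_ranks``, then is fixed at its best value before the
    next axis scans.  Ties break toward the smaller rank.  Returns the best
    configuration and the full (axis, k, mean_auc) table.
    """
    ranks = base_ranks
    folds = make_folds(graph, n_folds, seed)
    rows = []
    for axis in axes:
        grid = grids.get(axis)
        if not grid:
            raise ValueError(f"empty rank grid for axis {axis!r}")
        axis_rows = []
        for k in grid:
            candidate = ranks.with_rank(axis, k)
            result = cross_validate(graph, candidate, config, folds=folds)
            axis_rows.append({"axis": axis, "k": int(k), "mean_auc": result.mean_auc})
            logger.info("rank search %s=%d: mean_auc=%.4f", axis, k, result.mean_auc)
        rows.extend(axis_rows)
        # ties break toward the smaller rank
        best = min(axis_rows, key=lambda r: (-r["mean_auc"], r["k"]))
        best_k, best_auc = best["k"], best["mean_auc"]
        ranks = ranks.with_rank(axis, best_k)
        logger.info("rank search fixed %s=%d (mean_auc=%.4f)", axis, best_k, best_auc)
    return ranks, pd.DataFrame(rows)


def default_mirna_grid(stop: int = 2759, start: int = 10, step: int = 100) -> list[int]:
    """The coarse rank grid pattern used for axis searches: 10, 110, ... < stop."""
    return list(range(start, stop, step))


def ablate(
    graph: RelationGraph,
    drop_keys: list[RelationKey],
    ranks: RankConfig,
    config: FitConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Relation-ablation experiment: drop one side block at a time.

    The baseline CV runs on the full graph; each listed block is then removed
    and CV rerun with the identical fold assignment, reporting per-block mean
    AUC, pooled best MCC, and deltas against baseline.  Dropping the target
    block is an error.
    """
    folds = make_folds(graph, n_folds, seed)
    baseline = cross_validate(graph, ranks, config, folds=folds)
    rows = [
        {
            "dropped": "none",
            "mean_auc": baseline.mean_auc,
            "best_mcc": baseline.pooled.mcc,
            "delta_auc": 0.0,
            "delta_mcc": 0.0,
        }
    ]
    for key in drop_keys:
        if key == graph.target_key:
            raise ValueError("cannot ablate the target relation block")
        reduced = graph.drop_relation(key)
        result = cross_validate(reduced, ranks, config, folds=folds)
        rows.append(
            {
                "dropped": f"{key[0]}-{key[1]}",
                "mean_auc": result.mean_auc,
                "best_mcc": result.pooled.mcc,
                "delta_auc": result.mean_auc - baseline.mean_auc,
                "delta_mcc": result.pooled.mcc - baseline.pooled.mcc,
            }
        )
        logger.info(
            "ablation -%s-%s: mean_auc=%.4f (delta %.4f)",
            key[0],
            key[1],
            result.mean_auc,
            result.mean_auc - baseline.mean_auc,
        )
    return pd.DataFrame(rows)
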