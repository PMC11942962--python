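"""Protein-centric Fmax and pair-centric AUPR for multi-label prediction.

Fmax sweeps a decision threshold t over [0, 1]: a term is predicted for a
protein when its score is >= t. Per-protein precision is averaged over the
M(t) proteins with at least one prediction; per-protein recall is averaged
over all N proteins; Fmax is the maximum harmonic mean over the sweep (the
CAFA protein-centric protocol). Pair-centric AUPR flattens all protein x term
pairs and computes the micro-averaged average precision of the ranking, with
tied scores grouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import LabelTable

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTable",
    "MetricsResult",
    "precision_recall_at_t",
    "fmax",
    "fmax_exhaustive",
    "aupr_pair",
    "evaluate",
    "DEFAULT_THRESHOLD_GRID",
]

#: CAFA-style threshold grid: 0.00, 0.01, ..., 1.00.
DEFAULT_THRESHOLD_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class PredictionTable:
    """Protein x term score matrix with ground truth."""

    protein_ids: list[str]
    term_ids: list[str]
    scores: np.ndarray  # (N, F) in [0, 1]
    truth: np.ndarray  # (N, F) binary

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.truth = np.asarray(self.truth, dtype=np.int64)
        if self.scores.shape != self.truth.shape:
            raise ValueError("scores and truth shapes differ")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must lie in [0, 1]")

    def drop_empty_truth(self) -> "PredictionTable":
        """Remove proteins with no true terms (their recall is undefined)."""
        keep = self.truth.sum(axis=1) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropping %d protein(s) with empty truth sets", n_dropped)
        return PredictionTable(
            protein_ids=[p for p, k in zip(self.protein_ids, keep) if k],
            term_ids=list(self.term_ids),
            scores=self.scores[keep],
            truth=self.truth[keep],
        )


@dataclass
class MetricsResult:
    fmax: float
    best_threshold: float
    aupr: float
    n_proteins: int
    curve: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "best_threshold": self.best_threshold,
            "aupr": self.aupr,
            "n_proteins": self.n_proteins,
            "curve": self.curve,
        }


def precision_recall_at_t(table: PredictionTable, t: float) -> tuple[float, float, int]:
    """(precision(t), recall(t), M(t)) at one decision threshold.

    Precision averages only over the M(t) proteins with >= 1 prediction at t
    (0 with a flagged curve record when M(t) = 0); recall averages over all
    proteins. Proteins with empty truth sets must be dropped beforehand.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    pred = table.scores >= t
    tp = (pred & (table.truth == 1)).sum(axis=1)
    n_pred = pred.sum(axis=1)
    n_true = table.truth.sum(axis=1)
    has_pred = n_pred > 0
    M = int(has_pred.sum())
    precision = float((tp[has_pred] / n_pred[has_pred]).mean()) if M else 0.0
    recall = float((tp / n_true).mean())
    return precision, recall, M


def _f_measure(p: float, r: float) -> float:
    return 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)


def fmax(table: PredictionTable, thresholds: np.ndarray | None = None) -> MetricsResult:
    """Maximum F-measure over a threshold sweep, with the full curve.

    ``best_threshold`` is the smallest threshold achieving the maximum.
    """
    table = table.drop_empty_truth()
    if table.truth.shape[0] == 0:
        raise ValueError("no proteins with nonempty truth sets")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLD_GRID
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    curve = []
    best_f, best_t = -1.0, 0.0
    for t in thresholds:
        p, r, M = precision_recall_at_t(table, float(t))
        f = _f_measure(p, r)
        curve.append(
            {
                "t": float(t),
                "precision": p,
                "recall": r,
                "M": M,
                "f": f,
                "precision_undefined": M == 0,
            }
        )
        if f > best_f:
            best_f, best_t = f, float(t)
    return MetricsResult(
        fmax=best_f,
        best_threshold=best_t,
        aupr=aupr_pair(table),
        n_proteins=table.truth.shape[0],
        curve=curve,
    )


def fmax_exhaustive(table: PredictionTable) -> float:
    """Fmax over every distinct score cutpoint (plus 0) — the reference sweep
    against which the fixed grid is checked."""
    table = table.drop_empty_truth()
    cutpoints = np.unique(np.concatenate([[0.0], table.scores.ravel()]))
    best = 0.0
    for t in cutpoints:
        p, r, _ = precision_recall_at_t(table, float(t))
        best = max(best, _f_measure(p, r))
    return best


def aupr_pair(table: PredictionTable) -> float:
    """Micro-averaged average precision over all flattened protein-term pairs.

    AP = sum_k (R_k - R_{k-1}) P_k over the precision-recall step curve of
    the score ranking, with tied scores grouped.
    """
    scores = table.scores.ravel()
    truth = table.truth.ravel()
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("no positive protein-term pairs")
    order = np.argsort(-scores, kind="stable")
    scores, truth = scores[order], truth[order]
    # group tied scores
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        group_tp = int(truth[i:j].sum())
        tp_new = tp + group_tp
        seen_new = seen + (j - i)
        if group_tp:
            precision = tp_new / seen_new
            delta_recall = group_tp / n_pos
            ap += precision * delta_recall
        tp, seen = tp_new, seen_new
        i = j
    return float(ap)


def evaluate(table: PredictionTable, thresholds: np.ndarray | None = None) -> MetricsResult:
    """Full evaluation: Fmax with its curve plus pair-centric AUPR."""
    return fmax(table, thresholds)


def prediction_table_from_labels(
    scores: np.ndarray, labels: LabelTable
) -> PredictionTable:
    """Pair a score matrix with a LabelTable's truth."""
    return PredictionTable(
        protein_ids=list(labels.protein_ids),
        term_ids=list(labels.term_ids),
        scores=scores,
        truth=labels.truth,
    )
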