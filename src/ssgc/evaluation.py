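"""Positive-unlabeled ranking evaluation.

Only positive drug-disease pairs are observed, so the ROC sweep departs
from the fully-labeled convention: at a score threshold, an observed pair
above it is a true positive (else false negative) and an unobserved pair
above it is a false positive (else true negative). The resulting AUC equals
the probability that a random observed pair outranks a random unobserved
pair (Mann-Whitney form) when scores are untied.

Cross-validation partitions the positives into folds; per fold the held-out
positives are removed from training (including from the treatment-layer
similarities and the prior, which depend on the label matrix), the solver
is rerun, and the held-out positives are ranked against never-observed
pairs with the training positives excluded from the ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network_data import PairField

__all__ = [
    "FoldAssignment",
    "RocCurve",
    "CrossValidationResult",
    "make_folds",
    "modified_roc",
    "confusion_at_threshold",
    "cross_validate",
    "top_percent_retrieval",
    "gba_ratio",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the positive pairs into k folds of near-equal size."""

    positives: tuple[tuple[int, int], ...]
    fold_of: tuple[int, ...]
    k: int
    seed: int

    def fold_members(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in zip(self.positives, self.fold_of) if f == fold]


@dataclass
class RocCurve:
    """ROC polyline swept over descending score thresholds."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CrossValidationResult:
    fold_curves: list[RocCurve]
    pooled_curve: RocCurve
    fold_retrieved_top1pct: list[int]
    mean_fold_auc: float


def make_folds(Y: PairField, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition of the positive pairs into ``k`` folds.

    Fold sizes differ by at most one; reproducible from ``seed``.
    """
    ii, jj = np.nonzero(Y.values)
    positives = list(zip(ii.tolist(), jj.tolist()))
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives, have {len(positives)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    fold_of = [0] * len(positives)
    for rank, idx in enumerate(order):
        fold_of[idx] = rank % k
    return FoldAssignment(tuple(positives), tuple(fold_of), k, seed)


def _sweep(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Threshold sweep over the unique score values (with a +inf sentinel).

    ``labels`` is 1 for observed (positive) entries, 0 for unobserved.
    """
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # cumulative TP/FP after including each prefix of the ranking
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(1 - l_sorted)
    # collapse ties: keep only the last index of each distinct score
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    thresholds = np.concatenate(([np.inf], s_sorted[distinct]))
    tpr = np.concatenate(([0.0], tp[distinct] / n_pos))
    fpr = np.concatenate(([0.0], fp[distinct] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, tpr, fpr, auc)


def modified_roc(
    scores: PairField | np.ndarray,
    Y_eval: PairField | np.ndarray,
    mask: np.ndarray | None = None,
) -> RocCurve:
    """ROC under the positive-unlabeled convention.

    Observed pairs (``Y_eval == 1``) above a threshold are true positives,
    unobserved pairs above it false positives. ``mask`` (boolean, optional)
    restricts evaluation to the included entries — used to exclude training
    positives during cross-validation. A constant score field yields the
    two-endpoint curve with AUC 0.5.
    """
    s = scores.values if isinstance(scores, PairField) else np.asarray(scores, float)
    y = Y_eval.values if isinstance(Y_eval, PairField) else np.asarray(Y_eval, float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must share a shape")
    s, y = s.ravel(), (y.ravel() > 0).astype(float)
    if mask is not None:
        keep = np.asarray(mask, bool).ravel()
        s, y = s[keep], y[keep]
    return _sweep(s, y)


def confusion_at_threshold(
    scores: PairField | np.ndarray,
    Y_eval: PairField | np.ndarray,
    threshold: float = 0.05,
    mask: np.ndarray | None = None,
) -> dict[str, int]:
    """Single confusion matrix at a fixed score threshold (>= rule)."""
    s = scores.values if isinstance(scores, PairField) else np.asarray(scores, float)
    y = Y_eval.values if isinstance(Y_eval, PairField) else np.asarray(Y_eval, float)
    s, y = s.ravel(), (y.ravel() > 0)
    if mask is not None:
        keep = np.asarray(mask, bool).ravel()
        s, y = s[keep], y[keep]
    above = s >= threshold
    return {
        "tp": int((above & y).sum()),
        "fn": int((~above & y).sum()),
        "fp": int((above & ~y).sum()),
        "tn": int((~above & ~y).sum()),
    }


def top_percent_retrieval(
    scores: PairField,
    held_out: Sequence[tuple[int, int]],
    pct: float,
    exclude: Sequence[tuple[int, int]] = (),
) -> int:
    """Held-out positives ranked within the top ``pct`` percent of pairs.

    ``exclude`` (training positives) are removed from the ranking before the
    cutoff ``ceil(pct/100 * q)`` is applied; ties are broken by
    (drug_id, disease_id) lexicographic order, matching the score writer.
    """
    if not (0.0 < pct <= 100.0):
        raise ValueError("pct must be in (0, 100]")
    excl = set(exclude)
    drugs, diseases = scores.drugs.ids, scores.diseases.ids
    entries = [
        (-float(scores.values[i, j]), drugs[i], diseases[j], (i, j))
        for i in range(len(drugs))
        for j in range(len(diseases))
        if (i, j) not in excl
    ]
    entries.sort()
    q = len(entries)
    cutoff = math.ceil(pct / 100.0 * q)
    top = set(e[3] for e in entries[:cutoff])
    return sum(1 for p in held_out if p in top)


def cross_validate(
    train_predict: Callable[[PairField], PairField],
    Y: PairField,
    folds: FoldAssignment,
    top_pct: float = 1.0,
) -> CrossValidationResult:
    """Run per-fold training and pooled PU evaluation.

    ``train_predict`` maps a training label field (held-out positives set to
    0) to a score field; it must recompute everything that depends on the
    labels (treatment-layer similarities, prior). Held-out positives are the
    evaluation positives, never-observed pairs the negatives, and training
    positives are excluded from evaluation.
    """
    fold_curves: list[RocCurve] = []
    fold_retrieved: list[int] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for fold in range(folds.k):
        held = folds.fold_members(fold)
        Y_train = Y.copy()
        for i, j in held:
            Y_train.values[i, j] = 0.0
        scores = train_predict(Y_train)
        eval_mask = Y_train.values == 0  # training positives excluded
        y_eval = np.zeros_like(Y.values)
        for i, j in held:
            y_eval[i, j] = 1.0
        curve = modified_roc(scores.values, y_eval, mask=eval_mask)
        fold_curves.append(curve)
        train_pos = list(zip(*np.nonzero(Y_train.values)))
        fold_retrieved.append(
            top_percent_retrieval(scores, held, top_pct, exclude=train_pos)
        )
        keep = eval_mask.ravel()
        pooled_scores.append(scores.values.ravel()[keep])
        pooled_labels.append(y_eval.ravel()[keep])
    pooled_curve = _sweep(
        np.concatenate(pooled_scores), np.concatenate(pooled_labels)
    )
    mean_fold_auc = float(np.mean([c.auc for c in fold_curves]))
    return CrossValidationResult(
        fold_curves, pooled_curve, fold_retrieved, mean_fold_auc
    )


def gba_ratio(
    S: "np.ndarray | object", share: np.ndarray
) -> tuple[float, float, float | None]:
    """Guilt-by-association diagnostic.

    ``share[i, i']`` flags entity pairs that share at least one partner
    (drugs sharing a disease, diseases sharing a drug). Returns the mean
    off-diagonal similarity over sharing pairs, over non-sharing pairs, and
    their ratio (None when either set is empty, ratio undefined).
    """
    v = getattr(S, "values", S)
    v = np.asarray(v, float)
    share = np.asarray(share, bool)
    if share.shape != v.shape:
        raise ValueError("share mask must match the similarity shape")
    off = ~np.eye(v.shape[0], dtype=bool)
    same_mask = share & off
    diff_mask = ~share & off
    avg_same = float(v[same_mask].mean()) if same_mask.any() else float("nan")
    avg_diff = float(v[diff_mask].mean()) if diff_mask.any() else float("nan")
    if not same_mask.any() or not diff_mask.any() or avg_diff == 0.0:
        return avg_same, avg_diff, None
    return avg_same, avg_diff, avg_same / avg_diff


def share_partner_mask(Y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Boolean mask of entity pairs sharing >= 1 partner in a bipartite
    label matrix: drugs sharing a disease (``axis=0``) or diseases sharing a
    drug (``axis=1``)."""
    M = np.asarray(Y, float)
    if axis == 1:
        M = M.T
    co = M @ M.T
    return co > 0
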