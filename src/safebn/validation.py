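"""Model validation: k-fold cross-validation, confusion metrics, ROC/AUC.

The discretized cohort is split into k (default 10) near-equal folds;
for each fold, CPTs are learned on the remaining folds and every held-out
record is scored by the exact posterior probability of the accident state
given all of the record's non-outcome variables.  Scores are summarized
by a confusion matrix at a fixed threshold (default 0.5), by sensitivity
/ specificity / accuracy, and by the ROC curve with its area computed
from the Mann–Whitney rank statistic (midrank tie handling) — which
equals the trapezoidal area under the empirical ROC points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .learning import LearningConfig, em_learn
from .network import BayesianNetwork, ConditionalProbabilityTable, posterior

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "ValidationReport",
    "kfold_split",
    "cross_validate",
    "confusion_at_threshold",
    "confusion_metrics",
    "roc_auc",
    "validation_report",
]


@dataclass(frozen=True)
class FoldAssignment:
    n: int
    k: int
    seed: int
    folds: np.ndarray  # fold index per record

    def indices(self, fold: int) -> np.ndarray:
        return np.where(self.folds == fold)[0]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class ValidationReport:
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: np.ndarray
    auc: float
    threshold: float = 0.5
    fold_assignment: FoldAssignment | None = None


def kfold_split(
    n: int, k: int, seed: int, stratify_labels=None
) -> FoldAssignment:
    """Random balanced folds (sizes differ by at most one), deterministic
    given the seed; optional stratification keeps label proportions even
    across folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed n")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    if stratify_labels is None:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
    else:
        labels = np.asarray(stratify_labels)
        for value in pd.unique(labels):
            idx = np.where(labels == value)[0]
            perm = rng.permutation(idx.size)
            folds[idx[perm]] = np.arange(idx.size) % k
    return FoldAssignment(n, k, seed, folds)


def _score_records(
    network: BayesianNetwork,
    records: pd.DataFrame,
    target: str,
    positive_state: str,
) -> np.ndarray:
    """P(target = positive_state | all other observed variables), exact.

    When the target is a sink whose parents are all observed, the
    posterior reduces exactly to the CPT row — used as a fast path.
    """
    spec = network.nodes[target]
    pos_idx = spec.state_index(positive_state)
    other_cols = [c for c in records.columns if c != target and c in network.nodes]
    cpt = network.cpts[target]
    sink = not network.children(target)
    parents_observed = set(cpt.parent_order) <= set(other_cols) and not records[
        list(cpt.parent_order)
    ].isna().any().any()
    if sink and parents_observed:
        cards = [network.card(p) for p in cpt.parent_order]
        strides = ConditionalProbabilityTable.row_strides(cards)
        rows = np.zeros(len(records), dtype=np.int64)
        for p, s in zip(cpt.parent_order, strides):
            pidx = records[p].map({st: i for i, st in enumerate(network.nodes[p].states)})
            rows += pidx.to_numpy(dtype=np.int64) * s
        return cpt.table[rows, pos_idx]
    scores = np.empty(len(records))
    for i, (_, row) in enumerate(records.iterrows()):
        evidence = {
            c: row[c] for c in other_cols if not pd.isna(row[c])
        }
        scores[i] = posterior(network, target, evidence)[positive_state]
    return scores


def cross_validate(
    structure,
    data: pd.DataFrame,
    config: LearningConfig | None = None,
    target: str = "accident",
    positive_state: str = "yes",
    k: int = 10,
    seed: int = 0,
    stratify: bool = False,
):
    """Out-of-fold P(target = positive) for every record.

    Returns ``(scores, labels, fold_assignment)`` with labels as a 0/1
    array (1 = positive state).  Unseen parent configurations in a
    training fold are handled by the learner's pseudocount smoothing.
    """
    config = config or LearningConfig()
    n = len(data)
    labels01 = (data[target].to_numpy(dtype=object) == positive_state).astype(int)
    assignment = kfold_split(
        n, k, seed, stratify_labels=labels01 if stratify else None
    )
    scores = np.full(n, np.nan)
    for fold in range(k):
        test_idx = assignment.indices(fold)
        train = data.iloc[np.setdiff1d(np.arange(n), test_idx)]
        model = em_learn(structure, train, config)
        scores[test_idx] = _score_records(
            model.network, data.iloc[test_idx], target, positive_state
        )
    assert not np.isnan(scores).any(), "every record must be scored exactly once"
    return scores, labels01, assignment


class UndefinedMetricError(ValueError):
    """A confusion-matrix margin is empty, leaving a ratio undefined."""


def confusion_at_threshold(
    scores: np.ndarray, labels01: np.ndarray, threshold: float = 0.5
) -> ConfusionMatrix:
    """Threshold scores (>= threshold predicts positive) against labels."""
    pred = np.asarray(scores) >= threshold
    actual = np.asarray(labels01).astype(bool)
    return ConfusionMatrix(
        tp=int((pred & actual).sum()),
        fn=int((~pred & actual).sum()),
        fp=int((pred & ~actual).sum()),
        tn=int((~pred & ~actual).sum()),
    )


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as percents."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no actual positives: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no actual negatives: specificity undefined")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn)
    spec = 100.0 * cm.tn / (cm.tn + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


def roc_auc(scores, labels01) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    AUC uses the rank (Mann–Whitney) formulation with midranks for ties;
    the returned points are (FPR, TPR) at every distinct threshold
    (descending), prefixed by (0, 0), and their trapezoidal area equals
    the rank AUC exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels01).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    cut = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y_sorted)[cut]
    fps = np.cumsum(~y_sorted)[cut]
    points = np.column_stack([np.r_[0.0, fps / n0], np.r_[0.0, tps / n1]])
    return points, float(auc)


def validation_report(
    scores, labels01, threshold: float = 0.5, fold_assignment: FoldAssignment | None = None
) -> ValidationReport:
    cm = confusion_at_threshold(scores, labels01, threshold)
    sens, spec, acc = confusion_metrics(cm)
    points, auc = roc_auc(scores, labels01)
    return ValidationReport(cm, sens, spec, acc, points, auc, threshold, fold_assignment)
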