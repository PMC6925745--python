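"""k-fold cross-validated ROC/AUC evaluation of the network as an
accident-probability scorer.

Each fold learns structure and parameters on the other k-1 folds and
scores every held-out worker as P(target = positive | all of the
worker's other recorded variables). AUC is reported per fold, pooled
over the merged score vector, and as the mean of the fold values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bn.fit import fit_cpts
from .bn.model import DiscreteBN
from .bn.structure import learn_structure
from .config import LearnConfig
from .survey import SurveyTable


class RocError(ValueError):
    """Raised when a ROC curve or AUC is undefined."""


@dataclass
class FoldAssignment:
    """Partition of n records into k folds of near-equal size."""

    n: int
    k: int
    fold: np.ndarray
    seed: int

    def indices(self, fold_index: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold_index)


@dataclass
class RocResult:
    """Scores, ROC points and AUC summaries of a cross-validation run."""

    scores: np.ndarray
    labels: np.ndarray
    points: np.ndarray  # (m, 2) columns: 1-specificity, sensitivity
    auc: float  # pooled, on the merged scores
    fold_aucs: list[float] = field(default_factory=list)

    @property
    def mean_fold_auc(self) -> float:
        vals = [a for a in self.fold_aucs if not np.isnan(a)]
        return float(np.mean(vals)) if vals else float("nan")


def kfold_partition(n: int, k: int, seed: int) -> FoldAssignment:
    """Seeded uniform shuffle followed by a contiguous split.

    Fold sizes differ by at most one; when k divides n every fold holds
    exactly n/k records.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k, dtype=np.int64)
    sizes[: n % k] += 1
    start = 0
    for i, size in enumerate(sizes):
        fold[order[start : start + size]] = i
        start += size
    return FoldAssignment(n=n, k=k, fold=fold, seed=seed)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise RocError("AUC undefined: labels contain a single class")


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve points ((1-specificity, sensitivity)) over all
    score thresholds, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve.

    With ties given half credit this equals the Mann-Whitney rank
    statistic divided by n_pos * n_neg.
    """
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def score_records(
    bn: DiscreteBN, table: SurveyTable, target: str, positive=1
) -> np.ndarray:
    """P(target = positive | all other variables) for every record.

    With evidence on every non-target variable, the factors not
    involving the target cancel in the normalization, so the score is
    the renormalized product of the target's CPT and its children's
    CPTs — evaluated here vectorized over records. Identical to calling
    :func:`accidentbn.bn.posterior` per record.
    """
    var = bn.codebook[target]
    pos_idx = (
        var.categories.index(positive) if isinstance(positive, str)
        else int(positive) - 1
    )
    n = table.n
    card_t = bn.cardinality(target)
    enc = {}
    for node in bn.dag.nodes:
        if node == target:
            continue
        v = bn.codebook[node]
        col = table.column(node)
        e = col - 1
        if v.dkna:
            e = np.where(col == 0, v.n_categories, e)
        enc[node] = e

    log_score = np.zeros((n, card_t))
    involved = [target] + bn.dag.children(target)
    with np.errstate(divide="ignore"):
        for node in involved:
            cpt = bn.cpts[node]
            # gather CPT entries per record for each candidate target value
            for t_val in range(card_t):
                coords = tuple(
                    np.full(n, t_val, dtype=np.int64) if s == target else enc[s]
                    for s in cpt.scope
                )
                log_score[:, t_val] += np.log(cpt.table[coords])
    log_score -= log_score.max(axis=1, keepdims=True)
    probs = np.exp(log_score)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs[:, pos_idx]


def cross_validated_auc(
    table: SurveyTable,
    learn_config: LearnConfig | None = None,
    k: int = 10,
    seed: int = 0,
    target: str = "V1",
    positive=1,
) -> RocResult:
    """Learn and evaluate the network under k-fold cross validation.

    Returns per-fold AUCs, the pooled AUC over the merged held-out
    scores, and the merged score/label vectors in original row order.
    """
    cfg = learn_config or LearnConfig()
    cfg.validate()
    if k < 2:
        raise ValueError("k must be >= 2 for cross validation")
    var = table.codebook[target]
    pos_code = (
        var.code_of(positive) if isinstance(positive, str) else int(positive)
    )
    labels_all = (table.column(target) == pos_code).astype(int)
    _check_two_classes(labels_all)

    assignment = kfold_partition(table.n, k, seed)
    scores_all = np.empty(table.n, dtype=float)
    fold_aucs = []
    for i in range(k):
        test_idx = assignment.indices(i)
        train_idx = np.flatnonzero(assignment.fold != i)
        train = SurveyTable(
            table.codebook, table.data.iloc[train_idx].reset_index(drop=True)
        )
        test = SurveyTable(
            table.codebook, table.data.iloc[test_idx].reset_index(drop=True)
        )
        dag = learn_structure(
            train,
            score=cfg.score,
            max_parents=cfg.max_parents,
            seed=cfg.seed,
            restarts=cfg.restarts,
            whitelist=cfg.whitelist or None,
            blacklist=cfg.blacklist or None,
        )
        bn = fit_cpts(dag, train, pseudo_count=cfg.pseudo_count)
        fold_scores = score_records(bn, test, target, positive=pos_code)
        scores_all[test_idx] = fold_scores
        fold_labels = labels_all[test_idx]
        if len(np.unique(fold_labels)) < 2:
            fold_aucs.append(float("nan"))
        else:
            fold_aucs.append(auc(fold_scores, fold_labels))
    pooled = auc(scores_all, labels_all)
    pts = roc_points(scores_all, labels_all)
    return RocResult(
        scores=scores_all,
        labels=labels_all,
        points=pts,
        auc=pooled,
        fold_aucs=fold_aucs,
    )
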