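"""Performance metrics, ROC analysis and cross-validation protocols.

From the confusion counts the usual binary metrics are

    Sn = TP / (TP + FN),   Sp = TN / (TN + FP),
    Acc = (TP + TN) / (TP + FN + TN + FP),

reported as percentages (rounded half-up to two decimals only for display).
The ROC curve sweeps the decision threshold over the continuous log-ratio
scores; its trapezoidal area (auROC) equals the Mann-Whitney probability
that a random positive outscores a random negative, with ties counted half.

Two protocols are provided:

* jackknife (leave-one-out): every sample is predicted by a model fitted on
  all remaining samples, so exactly n models are trained and all n held-out
  predictions are pooled into one confusion matrix (micro-averaging) and
  one ROC;
* stratified k-fold feature selection: CFS best-first is run on each
  training fold, yielding per-fold subsets, a majority consensus subset and
  per-fold held-out accuracies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

import numpy as np

from . import naive_bayes as nb
from .cfs import AssociationMethod, best_first_search
from .features import FeatureMatrix, FeatureSubset, project_subset
from .seqio import PhavipError


class EvaluationError(PhavipError):
    """An evaluation contract is violated (single class, undefined metric, ...)."""


def round2(x: float) -> float:
    """Round half-up to 2 decimals, for displayed percentages."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise EvaluationError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


def metrics(confusion: ConfusionMatrix) -> tuple[float, float, float]:
    """(Sn, Sp, Acc) as unrounded percentages."""
    if confusion.n_pos == 0 or confusion.n_neg == 0:
        raise EvaluationError("metrics undefined without both classes")
    sn = 100.0 * confusion.tp / confusion.n_pos
    sp = 100.0 * confusion.tn / confusion.n_neg
    acc = 100.0 * (confusion.tp + confusion.tn) / (confusion.n_pos + confusion.n_neg)
    return sn, sp, acc


@dataclass(frozen=True)
class RocCurve:
    """ROC points from threshold +inf down to -inf.

    Starts at (0, 0), ends at (1, 1); both coordinates are non-decreasing.
    Tied scores collapse to a single point, so a tie group traces one
    diagonal segment.
    """

    fpr: np.ndarray
    tpr: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in zip(self.fpr, self.tpr):
                fh.write(f"{x:.17g}\t{y:.17g}\n")


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Threshold sweep over all distinct score values, descending."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length 1-d arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where a tie group of scores ends
    group_end = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    cum_tp = np.cumsum(y == 1)[group_end]
    cum_fp = np.cumsum(y == 0)[group_end]
    tpr = np.concatenate(([0.0], cum_tp / n_pos))
    fpr = np.concatenate(([0.0], cum_fp / n_neg))
    return RocCurve(fpr=fpr, tpr=tpr)


def auroc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Computed from rank sums; equal to the trapezoidal auROC and used as the
    independent second route in tests.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("auROC requires both classes")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    sn: float            # percentages, unrounded
    sp: float
    acc: float
    auroc: float
    theta_used: float
    protocol: Literal["jackknife", "kfold", "holdout"]
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "protocol": self.protocol,
            "confusion": {
                "tp": self.confusion.tp, "tn": self.confusion.tn,
                "fp": self.confusion.fp, "fn": self.confusion.fn,
            },
            "sn_percent": self.sn,
            "sp_percent": self.sp,
            "acc_percent": self.acc,
            "auroc": self.auroc,
            "theta": self.theta_used,
            "seed": self.seed,
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        c = self.confusion
        return (
            f"protocol: {self.protocol} (theta = {self.theta_used:g})\n"
            f"TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}\n"
            f"Sn = {round2(self.sn):.2f}%  Sp = {round2(self.sp):.2f}%  "
            f"Acc = {round2(self.acc):.2f}%  auROC = {self.auroc:.3f}\n"
        )


def report_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    theta: float,
    protocol: str,
    seed: int | None = None,
) -> EvalReport:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pred = scores >= theta
    confusion = ConfusionMatrix(
        tp=int((pred & (labels == 1)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )
    sn, sp, acc = metrics(confusion)
    return EvalReport(
        confusion=confusion, sn=sn, sp=sp, acc=acc,
        auroc=auroc(roc_curve(scores, labels)),
        theta_used=theta, protocol=protocol,  # type: ignore[arg-type]
        scores=scores, labels=labels, seed=seed,
    )


def jackknife_evaluate(
    matrix: FeatureMatrix,
    sigma_min: float = nb.DEFAULT_SIGMA_MIN,
    theta_policy: Literal["fixed", "tuned"] = "fixed",
    theta: float = 0.0,
    objective: str = "accuracy",
) -> EvalReport:
    """Leave-one-out evaluation: exactly n fits, n pooled held-out predictions.

    Under ``theta_policy="tuned"`` the threshold is re-tuned on each
    training fold; under ``fixed`` the supplied ``theta`` is used
    throughout.  The pooled continuous scores feed the ROC, so the auROC is
    threshold-independent.
    """
    matrix.require_labelled()
    n = matrix.n_rows
    y = matrix.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise EvaluationError("jackknife requires at least 2 samples per class")
    scores = np.empty(n)
    thetas = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        train = matrix.take_rows(all_idx[all_idx != i])
        model = nb.fit(train, sigma_min=sigma_min)
        if theta_policy == "tuned":
            thetas[i] = nb.tune_threshold(model, train, objective=objective)
        else:
            thetas[i] = theta
        scores[i] = nb.log_posterior_ratio(model, matrix.values[i])
    pred = scores >= thetas
    confusion = ConfusionMatrix(
        tp=int((pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )
    sn, sp, acc = metrics(confusion)
    theta_used = theta if theta_policy == "fixed" else float(np.mean(thetas))
    return EvalReport(
        confusion=confusion, sn=sn, sp=sp, acc=acc,
        auroc=auroc(roc_curve(scores, y)),
        theta_used=theta_used, protocol="jackknife",
        scores=scores, labels=y.copy(),
    )


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified split into k folds of test indices.

    Within each class the indices are shuffled by the seed and dealt
    round-robin, so class proportions are as even as integer counts allow.
    Every training fold must contain both classes (checked by callers that
    fit models).  With k = n each fold is a single sample -- the jackknife
    fold structure.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if k > n:
        raise EvaluationError(f"k={k} exceeds the number of samples n={n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for c in (1, 0):
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


@dataclass
class KFoldSelectionResult:
    fold_subsets: list[FeatureSubset]
    consensus: FeatureSubset
    fold_accuracy: list[float]   # held-out accuracy (fraction) per fold
    folds: list[np.ndarray] = field(default_factory=list)
    seed: int | None = None


def kfold_feature_selection(
    matrix: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    stale_limit: float = 5,
    method: AssociationMethod = "symmetrical-uncertainty",
    sigma_min: float = nb.DEFAULT_SIGMA_MIN,
) -> KFoldSelectionResult:
    """Run CFS best-first inside stratified k-fold cross-validation.

    Per fold: select a subset on the training rows, fit the classifier on
    those rows projected onto it, and record the held-out accuracy at
    theta = 0.  The consensus subset keeps features selected in at least
    ceil(k / 2) folds, in canonical feature order.
    """
    matrix.require_labelled()
    folds = stratified_folds(matrix.labels, k, seed)
    all_idx = np.arange(matrix.n_rows)
    fold_subsets: list[FeatureSubset] = []
    fold_acc: list[float] = []
    votes: dict[str, int] = {}
    for test_idx in folds:
        train_mask = ~np.isin(all_idx, test_idx)
        train = matrix.take_rows(all_idx[train_mask])
        test = matrix.take_rows(test_idx)
        if (train.labels == 1).sum() == 0 or (train.labels == 0).sum() == 0:
            raise EvaluationError("a training fold lost one class; reduce k")
        subset, _ = best_first_search(train, stale_limit=stale_limit, method=method)
        fold_subsets.append(subset)
        for name in subset.names:
            votes[name] = votes.get(name, 0) + 1
        model = nb.fit(project_subset(train, subset), sigma_min=sigma_min)
        pred = nb.predict_matrix(model, project_subset(test, subset))
        fold_acc.append(float((pred == test.labels).mean()))
    need = math.ceil(k / 2)
    canonical = {n: i for i, n in enumerate(matrix.feature_names)}
    consensus_names = sorted(
        (n for n, v in votes.items() if v >= need), key=canonical.__getitem__
    )
    return KFoldSelectionResult(
        fold_subsets=fold_subsets,
        consensus=FeatureSubset(tuple(consensus_names)),
        fold_accuracy=fold_acc,
        folds=folds,
        seed=seed,
    )
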