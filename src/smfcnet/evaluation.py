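"""Nested cross-validation, base-classifier ensembling, and metrics.

The evaluation protocol: subjects are split into 5 stratified outer folds.
For each outer fold, the training portion is repeatedly (5 times) split into
an internal training set (80%) and a validation set (20%); a 5-fold CV on
each internal training set trains 5 base classifiers, so 5 x 5 = 25 base
classifiers per outer fold. When a hyperparameter grid is supplied, each
combination is scored by mean validation accuracy and the best one's
classifiers are retained; with no grid the defaults are used directly. The
25 classifiers predict the held-out test subjects and a majority vote gives
the fold prediction. The whole procedure is repeated independently
(10 times by default) and metrics are reported as mean +/- std over
repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import SMFCNetClassifier

__all__ = [
    "CVPlan",
    "MetricsReport",
    "FoldEnsemble",
    "NestedCVResult",
    "majority_vote",
    "compute_metrics",
    "balanced_accuracy",
    "nested_cv",
    "ensemble_accuracy",
]


@dataclass
class CVPlan:
    """Cross-validation layout. Defaults follow the published protocol."""

    outer_folds: int = 5
    inner_folds: int = 5
    inner_repetitions: int = 5
    outer_repetitions: int = 10
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.inner_repetitions < 1 or self.outer_repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")

    @property
    def n_base_classifiers(self) -> int:
        return self.inner_folds * self.inner_repetitions


@dataclass
class MetricsReport:
    """Classification metrics per repetition with mean and std.

    ``per_repetition`` has one row per outer repetition with columns
    ACC/SEN/SPE/BAC/AUC/F1/PPV as fractions in [0, 1]; undefined ratios
    (zero denominators) are NaN, never silently 0.
    """

    per_repetition: pd.DataFrame
    mean: pd.Series = field(init=False)
    std: pd.Series = field(init=False)

    def __post_init__(self):
        self.mean = self.per_repetition.mean()
        self.std = self.per_repetition.std(ddof=1) if len(self.per_repetition) > 1 \
            else self.per_repetition.iloc[0] * np.nan

    def as_percent(self) -> pd.DataFrame:
        out = pd.DataFrame({"mean": self.mean * 100, "std": self.std * 100})
        return out.round(2)


@dataclass
class FoldEnsemble:
    """The 25 retained base classifiers of one outer fold."""

    classifiers: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    best_params: dict


@dataclass
class NestedCVResult:
    report: MetricsReport
    ensembles: list[list[FoldEnsemble]]  # [repetition][fold]
    plan: CVPlan


def majority_vote(votes) -> int:
    """Label predicted by more than half of an odd number of voters."""
    votes = np.asarray(votes)
    if votes.size % 2 == 0:
        raise ValueError(f"majority vote needs an odd number of voters, got {votes.size}")
    labels, counts = np.unique(votes, return_counts=True)
    return labels[counts.argmax()]


def balanced_accuracy(sen: float, spe: float) -> float:
    """BAC = (SEN + SPE) / 2, on whatever scale its inputs share."""
    return (sen + spe) / 2.0


def compute_metrics(tp: int, tn: int, fp: int, fn: int,
                    scores=None, labels=None) -> dict:
    """All reported metrics from a confusion table (class 1 = positive).

    ACC = (TP+TN)/total, SEN = TP/(TP+FN), SPE = TN/(TN+FP),
    BAC = (SEN+SPE)/2, PPV = TP/(TP+FP), F1 = 2*SEN*PPV/(SEN+PPV).
    AUC is the rank statistic over ``scores`` (positive-class score per
    subject) when given. Zero-denominator ratios are NaN.
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    acc = (tp + tn) / total
    sen = ratio(tp, tp + fn)
    spe = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    bac = balanced_accuracy(sen, spe)
    f1 = 2 * sen * ppv / (sen + ppv) if (sen + ppv) > 0 and not (math.isnan(sen) or math.isnan(ppv)) else math.nan
    auc = math.nan
    if scores is not None and labels is not None:
        labels = np.asarray(labels)
        if np.unique(labels).size == 2:
            auc = float(roc_auc_score(labels, np.asarray(scores)))
    return {"ACC": acc, "SEN": sen, "SPE": spe, "BAC": bac,
            "AUC": auc, "F1": f1, "PPV": ppv}


def _param_combinations(grid: dict | None):
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def _fit_inner_ensemble(X, y, train_idx, plan: CVPlan, make_classifier,
                        param_grid, rng) -> tuple[list, dict]:
    """Train the 25 base classifiers for one outer fold.

    For each of the ``inner_repetitions`` re-randomized internal-train /
    validation splits, every parameter combination is trained on the
    ``inner_folds`` folds of the internal training set and scored on the
    validation set; the combination with the best overall mean validation
    accuracy contributes its classifiers to the ensemble.
    """
    combos = _param_combinations(param_grid)
    # classifiers_per_combo[c][r] -> list of inner-fold classifiers
    clfs: dict[int, list] = {c: [] for c in range(len(combos))}
    val_scores = np.zeros(len(combos))
    y_tr = y[train_idx]
    for _ in range(plan.inner_repetitions):
        seed_split = int(rng.integers(2**31))
        internal, val = train_test_split(
            np.arange(train_idx.size), test_size=plan.validation_fraction,
            stratify=y_tr, random_state=seed_split)
        inner = StratifiedKFold(plan.inner_folds, shuffle=True,
                                random_state=int(rng.integers(2**31)))
        inner_splits = list(inner.split(internal, y_tr[internal]))
        for c, params in enumerate(combos):
            rep_clfs = []
            for tr_rel, _ in inner_splits:
                fit_idx = train_idx[internal[tr_rel]]
                clf = make_classifier(seed=int(rng.integers(2**31)), **params)
                clf.fit(X[fit_idx], y[fit_idx])
                rep_clfs.append(clf)
            val_idx = train_idx[val]
            preds = np.stack([clf.predict(X[val_idx]) for clf in rep_clfs])
            votes = np.apply_along_axis(majority_vote, 0, preds)
            val_scores[c] += float(np.mean(votes == y[val_idx]))
            clfs[c].extend(rep_clfs)
    best = int(np.argmax(val_scores))
    return clfs[best], combos[best]


def _default_factory(seed: int = 0, **params) -> SMFCNetClassifier:
    return SMFCNetClassifier(seed=seed, **params)


def _evaluate_repetition(ensembles: list[FoldEnsemble], X, y) -> dict:
    """Pool fold-level ensemble predictions into one repetition's metrics."""
    n = y.size
    pred = np.full(n, -1)
    score = np.full(n, np.nan)
    for fe in ensembles:
        votes = np.stack([clf.predict(X[fe.test_idx]) for clf in fe.classifiers])
        pred[fe.test_idx] = np.apply_along_axis(majority_vote, 0, votes)
        probs = np.stack([clf.predict_proba(X[fe.test_idx])[:, 1]
                          for clf in fe.classifiers])
        score[fe.test_idx] = probs.mean(axis=0)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return compute_metrics(tp, tn, fp, fn, scores=score, labels=y)


def nested_cv(X, y, plan: CVPlan | None = None, make_classifier=None,
              param_grid: dict | None = None) -> NestedCVResult:
    """Full nested cross-validation of a classifier over FCN stacks.

    Parameters
    ----------
    X : ndarray (n_subjects, d, N, N)
        Connectivity stacks.
    y : array of {0, 1}
        Diagnostic labels; class 1 is the positive (patient) class.
    plan : CVPlan
        Fold/repetition layout (defaults to the published 5x5x5x10 scheme).
    make_classifier : callable(seed=..., **params) -> estimator
        Base-classifier factory; defaults to :class:`SMFCNetClassifier`.
    param_grid : dict or None
        Optional hyperparameter grid searched by inner validation accuracy;
        ``None`` trains the defaults only.
    """
    plan = plan or CVPlan()
    make_classifier = make_classifier or _default_factory
    X = np.asarray(X)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("nested_cv requires exactly two classes")
    if plan.n_base_classifiers % 2 == 0:
        raise ValueError(
            f"inner_folds * inner_repetitions = {plan.n_base_classifiers} "
            "must be odd so majority votes cannot tie")
    min_class = min(np.sum(y == c) for c in np.unique(y))
    if min_class < plan.outer_folds:
        raise ValueError(
            f"smallest class has {min_class} subjects; cannot stratify "
            f"{plan.outer_folds} outer folds")
    rng = np.random.default_rng(plan.seed)
    all_ensembles: list[list[FoldEnsemble]] = []
    rows = []
    for _rep in range(plan.outer_repetitions):
        outer = StratifiedKFold(plan.outer_folds, shuffle=True,
                                random_state=int(rng.integers(2**31)))
        rep_ensembles = []
        for train_idx, test_idx in outer.split(X, y):
            assert np.intersect1d(train_idx, test_idx).size == 0
            classifiers, best = _fit_inner_ensemble(
                X, y, train_idx, plan, make_classifier, param_grid, rng)
            rep_ensembles.append(FoldEnsemble(
                classifiers=classifiers, train_idx=train_idx,
                test_idx=test_idx, best_params=best))
        rows.append(_evaluate_repetition(rep_ensembles, X, y))
        all_ensembles.append(rep_ensembles)
    report = MetricsReport(pd.DataFrame(rows))
    return NestedCVResult(report=report, ensembles=all_ensembles, plan=plan)


def ensemble_accuracy(result: NestedCVResult, X, y,
                      transform=None) -> float:
    """Mean test-set majority-vote accuracy of a fitted nested-CV ensemble.

    ``transform`` optionally maps the stack array before prediction (used by
    occlusion analyses); the stored fold structure guarantees every subject
    is scored only by classifiers that never saw it.
    """
    X = np.asarray(X)
    if transform is not None:
        X = transform(X)
    y = np.asarray(y)
    accs = []
    for rep_ensembles in result.ensembles:
        correct = 0
        total = 0
        for fe in rep_ensembles:
            votes = np.stack([clf.predict(X[fe.test_idx]) for clf in fe.classifiers])
            pred = np.apply_along_axis(majority_vote, 0, votes)
            correct += int(np.sum(pred == y[fe.test_idx]))
            total += fe.test_idx.size
        accs.append(correct / total)
    return float(np.mean(accs))
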