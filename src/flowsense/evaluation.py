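"""Classifier evaluation: cross-validation schemes, metrics, ROC,
transfer prediction and permutation importance.

Two interpretable classifiers are evaluated on the selected features:
maximum-likelihood logistic regression (discriminative) and Gaussian
naive Bayes (generative, per-class Gaussian likelihoods per feature with
training-frequency priors).  Participant dummies are NOT part of the
classifiers: the between-participant scheme evaluates generalisation to
an unseen person, whose identity is by construction unavailable.

Four validation schemes are supported; out-of-fold probabilities are
pooled (concatenated) across folds, and the reported confusion matrix
(cutoff 0.5), weighted precision/recall/F1 and AUC are computed on the
pooled predictions:

* ``between_participant`` -- leave-one-participant-out,
* ``stratified_10fold``   -- folds balanced jointly on participant and
  label as far as the counts allow (seeded),
* ``resubstitution``      -- train = test, the optimistic upper bound,
* ``leave_one_out``       -- per-row folds (the daily-use single-person
  mode).

AUC is the Mann-Whitney pair-counting statistic (ties count 1/2), and
permutation importance is the mean reduction in AUC when a single
feature column is shuffled, over many seeded shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "EvaluationError",
    "ConfusionMatrix",
    "MetricSet",
    "CVResult",
    "PermImportance",
    "FrozenLogisticModel",
    "CV_SCHEMES",
    "CLASSIFIERS",
    "train_classifier",
    "cross_validate",
    "metrics_from_confusion",
    "roc_auc",
    "roc_table",
    "transfer_predict",
    "permutation_importance",
]

CV_SCHEMES = ("between_participant", "stratified_10fold", "resubstitution", "leave_one_out")
CLASSIFIERS = ("logistic", "gaussian_nb")

PROB_CUTOFF = 0.5


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of observed x predicted classes ({no-flow, flow})."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=pd.Index(["no_flow", "flow"], name="observed"),
            columns=pd.Index(["no_flow", "flow"], name="predicted"),
        )


@dataclass(frozen=True)
class MetricSet:
    precision: float  # weighted by class support
    recall: float
    f1: float
    auc: float

    def __post_init__(self):
        for name in ("precision", "recall", "f1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise EvaluationError(f"{name} = {v} outside [0, 1]")
        if not (np.isnan(self.auc) or 0.0 <= self.auc <= 1.0):
            raise EvaluationError(f"auc = {self.auc} outside [0, 1]")


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: division by zero, reporting 0")
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix):
    """Support-weighted precision, recall and F1 from a confusion matrix.

    Per-class precision/recall/F1 are computed for both classes and
    averaged with the observed class supports as weights; the weighted
    recall therefore equals accuracy.
    """
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    per_class = {}
    for cls, tp, fp, fn in (
        (0, cm.tn, cm.fn, cm.fp),  # "no flow" treated as the positive label
        (1, cm.tp, cm.fp, cm.fn),
    ):
        precision = _safe_div(tp, tp + fp, f"class {cls} precision")
        recall = _safe_div(tp, tp + fn, f"class {cls} recall")
        f1 = _safe_div(2 * precision * recall, precision + recall, f"class {cls} F1")
        per_class[cls] = (precision, recall, f1)
    support = {0: cm.tn + cm.fp, 1: cm.fn + cm.tp}
    weights = {c: support[c] / cm.total for c in (0, 1)}
    precision = sum(weights[c] * per_class[c][0] for c in (0, 1))
    recall = sum(weights[c] * per_class[c][1] for c in (0, 1))
    f1 = sum(weights[c] * per_class[c][2] for c in (0, 1))
    return precision, recall, f1


def roc_auc(probabilities, labels) -> float:
    """AUC as the Mann-Whitney pair statistic (ties count 1/2)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC undefined: only one class present")
    ranks = rankdata(p)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def roc_table(probabilities, labels) -> pd.DataFrame:
    """TPR and TNR at every distinct probability threshold.

    A row's rule is predict flow iff probability >= threshold; thresholds
    enumerate the distinct predicted probabilities (plus one above the
    maximum, the predict-nothing corner).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(set(y)) < 2:
        raise EvaluationError("ROC undefined: only one class present")
    thresholds = np.concatenate([np.unique(p), [np.inf]])
    rows = []
    for t in thresholds:
        pred = (p >= t).astype(int)
        cm = ConfusionMatrix.from_predictions(y, pred)
        tpr = cm.tp / (cm.tp + cm.fn)
        tnr = cm.tn / (cm.tn + cm.fp)
        rows.append({"threshold": t, "tpr": tpr, "tnr": tnr})
    return pd.DataFrame(rows)


def train_classifier(kind: str, X, y):
    """Fit one of the two interpretable classifiers; returns an object
    with ``predict_proba`` giving P(flow | x) in column 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("training labels contain a single class")
    if kind == "logistic":
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    elif kind == "gaussian_nb":
        clf = GaussianNB(var_smoothing=1e-9)
    else:
        raise EvaluationError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    return clf


def _fold_indices(table: pd.DataFrame, scheme: str, seed: int,
                  label_col: str, group_col: str):
    """Yield (train_idx, test_idx) pairs of positional indices."""
    n = len(table)
    idx = np.arange(n)
    if scheme == "between_participant":
        participants = table[group_col].to_numpy()
        if len(pd.unique(participants)) < 2:
            raise EvaluationError("between-participant CV needs >= 2 participants")
        for p in pd.unique(participants):
            test = idx[participants == p]
            yield idx[participants != p], test
    elif scheme == "stratified_10fold":
        rng = np.random.default_rng(seed)
        n_folds = min(10, n)
        assignment = np.empty(n, dtype=int)
        # deal each (participant, label) cell round-robin across folds,
        # with a separate running offset per label so both the classes and
        # the participants spread as evenly as the counts allow
        offsets = {}
        cells = table.groupby([group_col, label_col], sort=True).indices
        for key in sorted(cells):
            label = key[1]
            members = np.array(cells[key])
            rng.shuffle(members)
            start = offsets.get(label, 0)
            for j, row in enumerate(members):
                assignment[row] = (start + j) % n_folds
            offsets[label] = (start + len(members)) % n_folds
        for f in range(n_folds):
            test = idx[assignment == f]
            if test.size:
                yield idx[assignment != f], test
    elif scheme == "resubstitution":
        yield idx, idx
    elif scheme == "leave_one_out":
        if n < 2:
            raise EvaluationError("leave-one-out needs >= 2 rows")
        for j in range(n):
            yield np.delete(idx, j), idx[j:j + 1]
    else:
        raise EvaluationError(f"unknown CV scheme {scheme!r}")


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one classifier under one scheme."""

    scheme: str
    classifier: str
    probabilities: pd.Series  # P(flow) per evaluated task
    labels: pd.Series
    confusion: ConfusionMatrix
    metrics: MetricSet
    skipped_folds: int = 0

    def summary(self) -> str:
        m = self.metrics
        return (
            f"{self.classifier} / {self.scheme}: "
            f"AUC {m.auc:.2f}  F1 {m.f1:.2f}  precision {m.precision:.2f}  "
            f"recall {m.recall:.2f}  (n = {self.confusion.total}"
            + (f", {self.skipped_folds} folds skipped)" if self.skipped_folds else ")")
        )


def _metricset(y_true, probs) -> MetricSet:
    cm = ConfusionMatrix.from_predictions(y_true, (np.asarray(probs) >= PROB_CUTOFF))
    precision, recall, f1 = metrics_from_confusion(cm)
    try:
        auc = roc_auc(probs, y_true)
    except EvaluationError:
        auc = float("nan")
    return cm, MetricSet(precision=precision, recall=recall, f1=f1, auc=auc)


def cross_validate(table: pd.DataFrame, scheme: str, classifier: str,
                   feature_cols: Sequence[str], seed: int = 0,
                   label_col: str = "flow",
                   group_col: str = "participant_id") -> CVResult:
    """Evaluate a classifier under one validation scheme.

    Test sets partition the rows (except resubstitution, which is
    in-sample); out-of-fold P(flow) are pooled and summarised.  A training
    fold containing a single class is skipped with a warning and its rows
    drop out of the pooled evaluation.
    """
    if scheme not in CV_SCHEMES:
        raise EvaluationError(f"unknown CV scheme {scheme!r}")
    table = table.reset_index(drop=True)
    X = table[list(feature_cols)].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=int)
    probs = np.full(len(table), np.nan)
    skipped = 0
    for train, test in _fold_indices(table, scheme, seed, label_col, group_col):
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"{scheme}: training fold with one class skipped")
            skipped += 1
            continue
        clf = train_classifier(classifier, X[train], y[train])
        probs[test] = clf.predict_proba(X[test])[:, 1]
    evaluated = ~np.isnan(probs)
    if not evaluated.any():
        raise EvaluationError("no fold could be evaluated")
    cm, metrics = _metricset(y[evaluated], probs[evaluated])
    return CVResult(
        scheme=scheme,
        classifier=classifier,
        probabilities=pd.Series(probs[evaluated], index=table.index[evaluated],
                                name="p_flow"),
        labels=pd.Series(y[evaluated], index=table.index[evaluated], name="flow"),
        confusion=cm,
        metrics=metrics,
        skipped_folds=skipped,
    )


@dataclass(frozen=True)
class FrozenLogisticModel:
    """A logistic model with frozen coefficients, for transfer prediction."""

    intercept: float
    coefficients: pd.Series  # indexed by feature name

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        missing = set(self.coefficients.index) - set(table.columns)
        if missing:
            raise EvaluationError(f"transfer table lacks features: {sorted(missing)}")
        eta = self.intercept + table[self.coefficients.index].to_numpy(
            dtype=float) @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def transfer_predict(model: FrozenLogisticModel, table: pd.DataFrame,
                     label_col: str = "flow"):
    """Apply frozen coefficients to a new study's feature table (no refit).

    Returns ``(MetricSet, probabilities)``.
    """
    probs = model.predict_proba(table)
    y = table[label_col].to_numpy(dtype=int)
    _, metrics = _metricset(y, probs)
    return metrics, pd.Series(probs, index=table.index, name="p_flow")


@dataclass
class PermImportance:
    """Mean and SD of the AUC reduction per shuffled feature."""

    importance: pd.DataFrame  # columns: mean_auc_drop, sd_auc_drop
    baseline_auc: float
    n_shuffles: int
    seed: int

    def summary(self) -> str:
        order = self.importance.sort_values("mean_auc_drop", ascending=False)
        lines = [f"permutation importance (baseline AUC {self.baseline_auc:.3f}, "
                 f"{self.n_shuffles} shuffles)"]
        for name, row in order.iterrows():
            lines.append(f"  {name:<24} {row.mean_auc_drop:+.3f} "
                         f"(sd {row.sd_auc_drop:.3f})")
        return "\n".join(lines)


def permutation_importance(classifier, X: pd.DataFrame, y,
                           n_shuffles: int = 1000, seed: int = 0) -> PermImportance:
    """AUC reduction when one feature column is shuffled, per feature.

    For each feature, ``n_shuffles`` seeded shuffles of that column alone
    are scored; the drop is baseline AUC minus shuffled AUC.
    """
    if n_shuffles < 1:
        raise EvaluationError("n_shuffles must be >= 1")
    if not isinstance(X, pd.DataFrame):
        raise EvaluationError("X must be a DataFrame with named feature columns")
    y = np.asarray(y, dtype=int)
    base = roc_auc(classifier.predict_proba(X.to_numpy(dtype=float))[:, 1], y)
    rng = np.random.default_rng(seed)
    rows = {}
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        drops = np.empty(n_shuffles)
        work = arr.copy()
        for t in range(n_shuffles):
            work[:, j] = rng.permutation(arr[:, j])
            drops[t] = base - roc_auc(classifier.predict_proba(work)[:, 1], y)
        rows[name] = {"mean_auc_drop": float(drops.mean()),
                      "sd_auc_drop": float(drops.std(ddof=0))}
    return PermImportance(
        importance=pd.DataFrame(rows).T,
        baseline_auc=base,
        n_shuffles=n_shuffles,
        seed=seed,
    )
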