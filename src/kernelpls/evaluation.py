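"""Cross-validated evaluation of a gene-selection pipeline.

Protocol: stratified k-fold cross-validation — 10 folds for two-class
problems, 5 for multi-class (small classes must appear in every training
and test split).  Inside each fold the selector is re-fit on the training
split only, so no information from held-out samples can leak into the
selected gene set.  Metrics: classification accuracy, area under the ROC
curve (two-class only, Mann-Whitney formulation), and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "EvalProtocol",
    "default_classifier",
    "auto_n_folds",
    "stratified_folds",
    "auc_two_class",
    "cohens_kappa",
    "confusion_counts",
    "evaluate_selection",
]


def default_classifier(knn_k: int = 5) -> KNeighborsClassifier:
    """k-nearest-neighbour classifier with the protocol default k=5."""
    return KNeighborsClassifier(n_neighbors=knn_k)


def auto_n_folds(labels) -> int:
    """10 folds for two-class designs, 5 for multi-class."""
    return 10 if len(set(np.asarray(labels).tolist())) == 2 else 5


@dataclass
class EvalProtocol:
    """Cross-validation protocol configuration.

    ``n_folds=None`` selects the class-count rule (10 two-class / 5
    multi-class).  ``classifier`` is any object with sklearn's fit/predict
    contract; it is cloned for every fold.
    """

    n_folds: int | None = None
    classifier: object = None
    knn_k: int = 5
    seed: int = 0

    def resolve_classifier(self):
        if self.classifier is not None:
            return clone(self.classifier)
        return default_classifier(self.knn_k)


def stratified_folds(labels, n_folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..n_folds-1 per sample).

    Every fold's class proportions match the global proportions within one
    sample.  Rejects fold counts larger than the smallest class, which
    would leave some test (or training) splits without that class.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class size "
            f"({counts.min()}); every class must be present in both the "
            "training and the test split of every fold"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment


def auc_two_class(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    ``labels`` must contain exactly two classes; the second class in sorted
    order is treated as positive unless labels are {0,1}/{-1,1}-like, in
    which case the larger value is positive either way.  Ties in the scores
    count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.shape[0] != 2:
        raise ValueError(
            f"AUC needs exactly 2 classes present, got {classes.shape[0]}"
        )
    pos = labels == classes[1]
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_counts(y_true, y_pred, classes=None) -> np.ndarray:
    """c x c confusion-count matrix (rows: true class, columns: predicted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion-count matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o =
    trace/total and expected agreement p_e from the row/column marginals.
    The degenerate case p_e = 1 (all mass in one cell row/column pattern)
    returns 1 for perfect agreement and 0 otherwise.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix has negative counts")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        import warnings

        warnings.warn(
            "degenerate marginals (expected agreement 1)", RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 if abs(p_o - 1.0) < 1e-12 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class EvaluationReport:
    """Per-fold metrics plus their mean and standard deviation."""

    per_fold: pd.DataFrame
    selected: list[list[str]] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean(numeric_only=True)

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(numeric_only=True, ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        out.loc["mean"] = self.mean
        out.loc["sd"] = self.sd
        return out


def _positive_scores(clf, X, classes) -> np.ndarray:
    """Continuous score for the positive (second) class, for the ROC curve."""
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        pos_col = list(clf.classes_).index(classes[1])
        return proba[:, pos_col]
    if hasattr(clf, "decision_function"):
        s = clf.decision_function(X)
        return s if s.ndim == 1 else s[:, list(clf.classes_).index(classes[1])]
    # fall back to hard predictions (AUC degrades to balanced accuracy-ish)
    return (clf.predict(X) == classes[1]).astype(float)


def evaluate_selection(
    X,
    labels,
    selector,
    k: int | None = None,
    protocol: EvalProtocol | None = None,
) -> EvaluationReport:
    """Cross-validate a selector + classifier pipeline.

    Within each fold the ``selector`` (an unfitted estimator with a
    ``top_k`` parameter and a fit/transform contract, e.g.
    :class:`~kernelpls.selection.KernelPLSSelector`) is cloned and re-fit
    on the training split only; the protocol classifier is then trained on
    the selected genes and scored on the held-out split.  Returns per-fold
    accuracy, AUC (two-class only) and Cohen's kappa.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    protocol = protocol or EvalProtocol()
    if k is not None:
        if k > X.shape[1]:
            raise ValueError(f"k={k} exceeds the number of genes {X.shape[1]}")
        selector = clone(selector).set_params(top_k=k)
    classes = np.unique(labels)
    two_class = classes.shape[0] == 2
    n_folds = protocol.n_folds or auto_n_folds(labels)
    assignment = stratified_folds(labels, n_folds, seed=protocol.seed)

    rows = []
    selected: list[list[str]] = []
    for fold in range(n_folds):
        test = assignment == fold
        train = ~test
        sel = clone(selector).fit(X[train], labels[train])
        support = sel.get_support()
        selected.append(
            sel.selected_gene_ids()
            if hasattr(sel, "selected_gene_ids")
            else list(np.nonzero(support)[0])
        )
        clf = protocol.resolve_classifier()
        clf.fit(X[np.ix_(train, support)], labels[train])
        y_pred = clf.predict(X[np.ix_(test, support)])
        y_true = labels[test]
        acc = float(np.mean(y_pred == y_true))
        cm = confusion_counts(y_true, y_pred, classes=classes)
        kappa = cohens_kappa(cm)
        row = {"fold": fold, "acc": acc, "kappa": kappa}
        if two_class:
            scores = _positive_scores(clf, X[np.ix_(test, support)], classes)
            row["auc"] = auc_two_class(scores, y_true)
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return EvaluationReport(per_fold=per_fold, selected=selected)
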