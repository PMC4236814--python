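"""Key ancestry-predictive eQTL selection.

Candidate eQTL genotype columns are screened by greedy forward selection
inside a flexible discriminant analysis (linear optimal scoring, equivalent
to linear discriminant analysis on additive genotype codes): at each step
the SNP giving the largest increment in training accuracy joins the panel,
ties broken by the smallest within- over between-population sum-of-squares
ratio, and selection stops at perfect accuracy or an increment below
``stop_delta``.  A stratified outer 10-fold cross-validation repeats the
whole selection per fold and keeps the fold-model with the highest testing
accuracy as the final panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


def _fit_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain >= 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 training samples")
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            lda.fit(X, y)
        except (np.linalg.LinAlgError, IndexError, FloatingPointError):
            # degenerate (e.g. zero) within-class scatter: ridge jitter
            scale = max(float(np.abs(X).max()), 1.0)
            jitter = 1e-8 * scale * np.random.default_rng(0).standard_normal(X.shape)
            lda.fit(X + jitter, y)
    return lda


def fda_fit(X, labels):
    """Fit linear-basis FDA (== LDA) and report training accuracy.

    Returns (fitted model, training accuracy).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    lda = _fit_lda(X, y)
    acc = float(np.mean(lda.predict(X) == y))
    return lda, acc


def sums_of_squares_ratio(genotypes, labels) -> float:
    """SS_within / SS_between of genotype codes across classes.

    Used only as the forward-selection tie-breaker; +inf when the class
    means coincide (no between-class separation).
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    grand = g.mean()
    ss_b = 0.0
    ss_w = 0.0
    for c in classes:
        sub = g[y == c]
        ss_b += sub.size * (sub.mean() - grand) ** 2
        ss_w += float(((sub - sub.mean()) ** 2).sum())
    if ss_b == 0:
        return float("inf")
    return ss_w / ss_b


def forward_select(
    X_candidates,
    labels,
    candidate_ids=None,
    stop_delta: float = 0.001,
):
    """Greedy forward selection of genotype columns by training accuracy.

    Returns (ordered list of selected ids, accuracy trace).  Accuracy before
    the first step counts as 0, so a first marker is always admitted.
    """
    X = np.asarray(X_candidates, dtype=float)
    y = np.asarray(labels)
    m = X.shape[1]
    if m == 0:
        raise ValueError("candidate set is empty")
    ids = list(candidate_ids) if candidate_ids is not None else [f"snp{j}" for j in range(m)]
    remaining = list(range(m))
    panel: list[int] = []
    trace: list[float] = []
    acc_prev = 0.0
    while remaining:
        best = None  # (accuracy, -? ) choose max acc, tie min ratio, tie lexicographic id
        for j in remaining:
            cols = panel + [j]
            _, acc = fda_fit(X[:, cols], y)
            ratio = sums_of_squares_ratio(X[:, j], y)
            if best is None or (
                acc > best[0] + 1e-12
                or (abs(acc - best[0]) <= 1e-12 and ratio < best[1] - 1e-12)
                or (abs(acc - best[0]) <= 1e-12 and abs(ratio - best[1]) <= 1e-12 and ids[j] < ids[best[2]])
            ):
                best = (acc, ratio, j)
        acc_new, _, j_best = best
        if acc_new - acc_prev < stop_delta:
            break
        panel.append(j_best)
        remaining.remove(j_best)
        trace.append(acc_new)
        acc_prev = acc_new
        if acc_new >= 1.0:
            break
    return [ids[j] for j in panel], trace


class ForwardSelectFDA(BaseEstimator, ClassifierMixin):
    """Forward-selection FDA classifier over genotype columns.

    Parameters
    ----------
    stop_delta : float
        Minimum training-accuracy increment to keep adding markers.
    candidate_ids : sequence or None
        Names for the columns of X (used for reporting and tie-breaks).

    Attributes
    ----------
    selected_ : ordered list of selected column names.
    selected_idx_ : their column indices.
    trace_ : training accuracy after each step (non-decreasing).
    model_ : the LDA fit on the selected columns.
    """

    def __init__(self, stop_delta: float = 0.001, candidate_ids=None):
        self.stop_delta = stop_delta
        self.candidate_ids = candidate_ids

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        ids = (
            list(self.candidate_ids)
            if self.candidate_ids is not None
            else [f"snp{j}" for j in range(X.shape[1])]
        )
        self.selected_, self.trace_ = forward_select(X, y, ids, self.stop_delta)
        self.selected_idx_ = [ids.index(s) for s in self.selected_]
        self.model_ = _fit_lda(X[:, self.selected_idx_], y) if self.selected_idx_ else None
        self.classes_ = np.unique(y)
        self._majority = self.classes_[
            int(np.argmax([np.sum(y == c) for c in self.classes_]))
        ]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.model_ is None:
            return np.full(X.shape[0], self._majority)
        return self.model_.predict(X[:, self.selected_idx_])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class ClassifierPanel:
    """Outcome of the nested 10-fold selection."""

    snp_ids: list[str]
    coefficients: np.ndarray | None
    trace: list[float]
    fold_train_accuracy: list[float]
    fold_test_accuracy: list[float]
    fold_panels: list[list[str]] = field(default_factory=list)
    chosen_fold: int = 0

    @property
    def best_test_accuracy(self) -> float:
        return self.fold_test_accuracy[self.chosen_fold]


def nested_cv_classify(
    X,
    labels,
    snp_ids=None,
    k: int = 10,
    seed: int | None = None,
    stop_delta: float = 0.001,
) -> ClassifierPanel:
    """Outer stratified k-fold CV around forward-selection FDA.

    Each fold runs the full selection on its training portion and scores the
    held-out portion; the fold-model with the highest testing accuracy is
    the panel (ties: smaller panel, then lower fold index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"n={n} < k={k} folds")
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(X.shape[1])]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn("a class has fewer samples than folds; fold sizes rebalanced")
        k = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_models: list[ForwardSelectFDA] = []
    train_acc: list[float] = []
    test_acc: list[float] = []
    panels: list[list[str]] = []
    traces: list[list[float]] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = ForwardSelectFDA(stop_delta=stop_delta, candidate_ids=ids)
        clf.fit(X[train_idx], y[train_idx])
        fold_models.append(clf)
        train_acc.append(clf.trace_[-1] if clf.trace_ else float(np.mean(
            np.full(len(train_idx), clf._majority) == y[train_idx])))
        test_acc.append(clf.score(X[test_idx], y[test_idx]))
        panels.append(clf.selected_)
        traces.append(clf.trace_)
    order = sorted(
        range(len(fold_models)),
        key=lambda i: (-test_acc[i], len(panels[i]), i),
    )
    best = order[0]
    chosen = fold_models[best]
    coefs = chosen.model_.coef_ if chosen.model_ is not None else None
    return ClassifierPanel(
        snp_ids=panels[best],
        coefficients=coefs,
        trace=traces[best],
        fold_train_accuracy=train_acc,
        fold_test_accuracy=test_acc,
        fold_panels=panels,
        chosen_fold=best,
    )


def candidate_sets(per_pop_eqtl: dict[str, set]) -> dict[str, set]:
    """The three candidate constructions over per-population eQTL lists.

    union: markers found in any population; intersection: in all;
    specific: in exactly one (the symmetric difference of the lists).
    """
    pops = sorted(per_pop_eqtl)
    union = set().union(*(per_pop_eqtl[p] for p in pops))
    inter = set(per_pop_eqtl[pops[0]])
    for p in pops[1:]:
        inter &= per_pop_eqtl[p]
    specific = {
        m for m in union if sum(m in per_pop_eqtl[p] for p in pops) == 1
    }
    return {"union": union, "intersection": inter, "specific": specific}
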