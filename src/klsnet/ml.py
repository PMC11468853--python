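"""Nested cross-validated classification of subjects from connectome features.

Three classifiers — L2 logistic regression (LR), linear-kernel SVM, and
random forest (RF) — are evaluated with stratified nested cross-validation:
a 10-fold outer loop estimates generalization; within each outer training
fold a min-max scaler is fit (never touching the test fold) and a stratified
5-fold inner loop picks the hyperparameter maximising fold-averaged accuracy
(LR/SVM: C over 2^-5 .. 32; RF: n_estimators 10..200 step 10).  Out-of-fold
predictions are pooled across outer folds before computing accuracy, ROC
AUC, sensitivity (patient recall; patients are the positive class) and
specificity.  Significance of accuracy and AUC comes from label-permutation
tests with the (1 + b)/(1 + P) estimator, and feature contributions are the
mean linear weights (LR/SVM) or impurity importances (RF) across outer
folds.

The RF hyperparameter search exploits that, for a fixed random state,
scikit-learn's forest with ``n_estimators=k`` consists of the first k trees
of the forest with the maximal tree count, so a single maximal forest per
inner fold scores the whole grid exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CVResult",
    "DEFAULT_GRIDS",
    "MODELS",
    "nested_cv",
    "permutation_significance",
    "feature_contributions",
    "roc_curve",
]

MODELS = ("lr", "svm", "rf")

DEFAULT_GRIDS = {
    "lr": [float(2.0**k) for k in range(-5, 6)],      # C: 2^-5 .. 32
    "svm": [float(2.0**k) for k in range(-5, 6)],
    "rf": list(range(10, 201, 10)),                    # n_estimators
}


@dataclass
class CVResult:
    model: str
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    confusion: tuple[int, int, int, int]               # tn, fp, fn, tp
    y_true: np.ndarray = field(repr=False, default=None)
    scores: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)
    best_params: list = field(repr=False, default_factory=list)
    contributions: np.ndarray = field(repr=False, default=None)
    feature_names: tuple[str, ...] = ()
    p_accuracy: float = float("nan")
    p_auc: float = float("nan")


def _make_model(model: str, param, seed: int):
    if model == "lr":
        # liblinear's default penalty is L2
        return LogisticRegression(C=param, solver="liblinear",
                                  max_iter=1000, random_state=seed)
    if model == "svm":
        return SVC(kernel="linear", C=param, random_state=seed)
    if model == "rf":
        return RandomForestClassifier(n_estimators=int(param), random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _contribution(model_name: str, clf) -> np.ndarray:
    if model_name == "rf":
        return clf.feature_importances_.astype(float)
    return np.asarray(clf.coef_).ravel().astype(float)


def _inner_select_linear(model, grid, Xtr, ytr, inner, seed):
    acc = np.zeros(len(grid))
    for tr_i, va_i in inner.split(Xtr, ytr):
        for gi, C in enumerate(grid):
            clf = _make_model(model, C, seed)
            clf.fit(Xtr[tr_i], ytr[tr_i])
            acc[gi] += float(np.mean(clf.predict(Xtr[va_i]) == ytr[va_i]))
    return grid[int(np.argmax(acc))]


_MAX_INT = np.iinfo(np.int32).max


def _grow_forest_trees(X32, y, n_trees: int, seed: int) -> list:
    """Grow the exact trees RandomForestClassifier(n_trees, random_state=seed)
    would fit, without the estimator-level bookkeeping.

    Replicates the forest's seed spawning (one randint per tree) and its
    bootstrap-by-sample-weight scheme, so the k-tree prefix reproduces the
    k-tree forest bit for bit (asserted in the test suite).  ``X32`` must be
    C-contiguous float32, as inside a fitted forest.
    """
    rs = np.random.RandomState(seed)
    n = X32.shape[0]
    trees = []
    for _ in range(n_trees):
        t = DecisionTreeClassifier(
            max_features="sqrt", random_state=rs.randint(_MAX_INT)
        )
        idx = np.random.RandomState(t.random_state).randint(0, n, n)
        t.fit(X32, y, sample_weight=np.bincount(idx, minlength=n),
              check_input=False)
        trees.append(t)
    return trees


def _inner_select_rf(grid, Xtr, ytr, inner, seed):
    """Score the whole n_estimators grid from one maximal forest per fold."""
    max_trees = int(max(grid))
    acc = np.zeros(len(grid))
    X32 = np.ascontiguousarray(Xtr, dtype=np.float32)
    for tr_i, va_i in inner.split(Xtr, ytr):
        trees = _grow_forest_trees(X32[tr_i], ytr[tr_i], max_trees, seed)
        classes = trees[0].classes_
        # per-tree class probabilities on the validation slice
        tree_proba = np.stack(
            [t.predict_proba(X32[va_i], check_input=False) for t in trees]
        )                                              # (trees, n_val, n_cls)
        cum = np.cumsum(tree_proba, axis=0)
        for gi, k in enumerate(grid):
            mean_proba = cum[int(k) - 1] / int(k)
            pred = classes[np.argmax(mean_proba, axis=1)]
            acc[gi] += float(np.mean(pred == ytr[va_i]))
    return grid[int(np.argmax(acc))]


def _scores(model_name: str, clf, X: np.ndarray) -> np.ndarray:
    if model_name == "svm":
        return clf.decision_function(X)
    proba = clf.predict_proba(X)
    pos = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos]


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    outer_k: int = 10,
    inner_k: int = 5,
    grid: list | None = None,
    rng_seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> CVResult:
    """Run nested cross-validation for one classifier.

    ``y`` is binary with 1 = patient (the positive class).  Deterministic for
    a fixed ``rng_seed``: the same seed reproduces folds, fitted models and
    metrics bit-for-bit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (subjects, features) aligned with y")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes coded 0/1")
    if min((y == 1).sum(), (y == 0).sum()) < outer_k:
        raise ValueError("need at least outer_k subjects per class")
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    grid = list(DEFAULT_GRIDS[model] if grid is None else grid)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))

    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 + 2 * outer_k) % (2**31)
    outer = StratifiedKFold(outer_k, shuffle=True, random_state=int(seeds[0]))

    n = X.shape[0]
    pooled_pred = np.empty(n, dtype=int)
    pooled_score = np.empty(n, dtype=float)
    best_params = []
    contribs = []
    # inputs are validated above and hyperparameters come from fixed grids,
    # so skip scikit-learn's per-fit re-validation (it dominates runtime on
    # data this small)
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for fold, (tr, te) in enumerate(outer.split(X, y)):
            scaler = MinMaxScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            ytr = y[tr]
            inner = StratifiedKFold(
                inner_k, shuffle=True, random_state=int(seeds[2 + fold])
            )
            fit_seed = int(seeds[2 + outer_k + fold])
            if model == "rf":
                best = _inner_select_rf(grid, Xtr, ytr, inner, fit_seed)
            else:
                best = _inner_select_linear(model, grid, Xtr, ytr, inner, fit_seed)
            clf = _make_model(model, best, fit_seed)
            clf.fit(Xtr, ytr)
            pooled_pred[te] = clf.predict(Xte)
            pooled_score[te] = _scores(model, clf, Xte)
            best_params.append(best)
            contribs.append(_contribution(model, clf))

    tp = int(((pooled_pred == 1) & (y == 1)).sum())
    tn = int(((pooled_pred == 0) & (y == 0)).sum())
    fp = int(((pooled_pred == 1) & (y == 0)).sum())
    fn = int(((pooled_pred == 0) & (y == 1)).sum())
    return CVResult(
        model=model,
        accuracy=(tp + tn) / n,
        auc=float(roc_auc_score(y, pooled_score)),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        confusion=(tn, fp, fn, tp),
        y_true=y.copy(),
        scores=pooled_score,
        predictions=pooled_pred,
        best_params=best_params,
        contributions=np.mean(contribs, axis=0),
        feature_names=tuple(feature_names),
    )


def permutation_significance(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    n_perm: int = 5000,
    rng_seed: int = 0,
    observed: CVResult | None = None,
    **cv_kwargs,
) -> tuple[float, float]:
    """Permutation p values for pooled accuracy and AUC.

    Labels are shuffled ``n_perm`` times and the *full* nested CV is re-run
    on each shuffle; p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable permutation p values")
    if observed is None:
        observed = nested_cv(X, y, model, rng_seed=rng_seed, **cv_kwargs)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xC0FFEE]))
    ge_acc = 0
    ge_auc = 0
    y = np.asarray(y).astype(int)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        res = nested_cv(X, yp, model, rng_seed=rng_seed, **cv_kwargs)
        ge_acc += res.accuracy >= observed.accuracy
        ge_auc += res.auc >= observed.auc
    p_acc = (1 + ge_acc) / (1 + n_perm)
    p_auc = (1 + ge_auc) / (1 + n_perm)
    observed.p_accuracy = p_acc
    observed.p_auc = p_auc
    return p_acc, p_auc


def feature_contributions(
    results: dict[str, CVResult], top_fraction: float = 0.20
) -> list[str]:
    """Features in the top fraction by |contribution| in *every* model.

    Per model, features are ranked by absolute mean weight (LR/SVM) or mean
    importance (RF) and the top ``ceil(top_fraction * F)`` kept; the
    intersection across models is returned (possibly empty), in the original
    feature order.
    """
    names = None
    tops = []
    for res in results.values():
        if names is None:
            names = res.feature_names
        elif res.feature_names != names:
            raise ValueError("models were fit on different feature sets")
        k = ceil(top_fraction * len(names))
        order = np.argsort(-np.abs(res.contributions), kind="stable")
        tops.append(set(order[:k].tolist()))
    common = set.intersection(*tops) if tops else set()
    return [names[i] for i in sorted(common)]


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """ROC sweep: (fpr, tpr, auc).  AUC is invariant to monotone transforms."""
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, float(roc_auc_score(labels, scores))
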