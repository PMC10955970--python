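"""Classifier training and repeated cross-validated ROC/AUC evaluation.

Feature categories are weighted in the ratio polarization : holographic :
texture : FPS (default 4:2:2:2) after per-column standardization: every
column is multiplied by its category weight divided by the number of
features in that category, so a category's total mass follows the ratio
regardless of how many scalars it contributes.  Category mapping:
C4-C7 -> polarization, C8 -> holographic, C1+C3 -> texture, C2 -> FPS.

Evaluation repeats stratified k-fold cross-validation R times with
reshuffled folds; out-of-fold scores are pooled per repeat into
one-vs-rest ROC curves and a macro (unweighted class-mean) AUC, and the
mean and variance of the macro AUC across repeats are reported.  All
imputation, standardization and weighting are fitted on training folds
only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from holopol.io_core import ClassifierSettings, CVSettings, FeatureTable

logger = logging.getLogger("holopol.classify")

#: feature-category -> group-tag mapping used by the 4:2:2:2 weighting
CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "polarization": ("C4", "C5", "C6", "C7"),
    "holographic": ("C8",),
    "texture": ("C1", "C3"),
    "fps": ("C2",),
}
CATEGORY_ORDER = ("polarization", "holographic", "texture", "fps")


def category_of(tag: str) -> str:
    for cat, tags in CATEGORY_GROUPS.items():
        if tag in tags:
            return cat
    raise ValueError(f"group tag {tag!r} belongs to no category")


class CategoryWeighter(BaseEstimator, TransformerMixin):
    """Standardize columns, then scale each by its category weight.

    ``group_tags`` gives the C1..C8 tag of every column; the weight of a
    column in category c is ratio[c] / n_columns(c).  Fitting uses only
    the data passed to :meth:`fit` (training folds under CV).
    """

    def __init__(self, group_tags: Sequence[str], ratio: Sequence[float] = (4, 2, 2, 2),
                 standardize: bool = True):
        self.group_tags = list(group_tags)
        self.ratio = tuple(ratio)
        self.standardize = standardize

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.group_tags):
            raise ValueError("column count does not match group_tags")
        cats = [category_of(t) for t in self.group_tags]
        present = set(cats)
        ratio = dict(zip(CATEGORY_ORDER, self.ratio))
        counts = {c: cats.count(c) for c in present}
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        if not self.standardize:
            self.mean_ = np.zeros_like(self.mean_)
            self.scale_ = np.ones_like(self.scale_)
        self.weights_ = np.array([ratio[c] / counts[c] for c in cats])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) / self.scale_ * self.weights_


def weight_features(table: FeatureTable, ratio: Sequence[float] = (4, 2, 2, 2)) -> FeatureTable:
    """Return a table with standardized, category-weighted feature columns.

    All four categories must be present.  This fits the weighting on the
    whole table (exploratory use); :func:`cross_validate` refits it on
    training folds only.
    """
    cols = table.feature_columns
    tags = [table.groups[c] for c in cols]
    present = {category_of(t) for t in tags}
    missing = set(CATEGORY_ORDER) - present
    if missing:
        raise ValueError(f"feature categories missing from table: {sorted(missing)}")
    w = CategoryWeighter(tags, ratio).fit(table.matrix())
    df = table.df.copy()
    df[cols] = w.transform(table.matrix())
    return FeatureTable(df, dict(table.groups))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """One-vs-rest ROC by descending threshold sweep; trapezoid AUC.

    ``labels`` is boolean (positive class); tied scores share one
    threshold.  Returns (fpr, tpr, auc) with curves starting at (0, 0)
    and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    P = int(labels.sum())
    N = int(labels.size - P)
    if P == 0 or N == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tied group
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, s.size - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(~y)[idx]
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    return roc_curve(scores, labels)[2]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


@dataclass
class ClassifierSpec:
    """One of the four supported classifier families with its presets.

    ESD is a random-subspace ensemble of linear discriminants (30
    learners on ceil(d/2)-dimensional subspaces, averaged posteriors);
    KNN uses k=10 distance-weighted votes; NN one hidden layer of 25
    logistic-output units; SVM a linear kernel with one-vs-rest pooled
    decision values.  ``params`` overrides the presets.
    """

    kind: str = "SVM"
    params: dict = field(default_factory=dict)
    standardize: bool = True
    ratio: tuple[float, float, float, float] = (4.0, 2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("ESD", "KNN", "NN", "SVM"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @classmethod
    def from_settings(cls, settings: ClassifierSettings) -> "ClassifierSpec":
        return cls(kind=settings.kind, standardize=settings.standardize,
                   ratio=tuple(settings.ratio))


def _make_estimator(spec: ClassifierSpec, n_features: int, seed: int):
    p = dict(spec.params)
    if spec.kind == "SVM":
        return SVC(kernel=p.pop("kernel", "linear"),
                   C=p.pop("C", 1.0),
                   decision_function_shape="ovr",
                   random_state=seed, **p)
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 10),
                                    weights=p.pop("weights", "distance"), **p)
    if spec.kind == "NN":
        return MLPClassifier(hidden_layer_sizes=p.pop("hidden_layer_sizes", (25,)),
                             max_iter=p.pop("max_iter", 500),
                             random_state=seed, **p)
    # ESD: random-subspace ensemble of linear discriminant learners
    max_features = p.pop("max_features", max(1, math.ceil(n_features / 2)))
    return BaggingClassifier(
        estimator=LinearDiscriminantAnalysis(),
        n_estimators=p.pop("n_estimators", 30),
        max_features=max_features,
        bootstrap=False,
        bootstrap_features=False,
        random_state=seed,
        **p,
    )


def build_pipeline(spec: ClassifierSpec, group_tags: Sequence[str], seed: int,
                   weighting: bool = True) -> Pipeline:
    ratio = spec.ratio if weighting else (1.0, 1.0, 1.0, 1.0)
    steps = [
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
        ("weight", CategoryWeighter(group_tags, ratio, standardize=spec.standardize)),
        ("clf", _make_estimator(spec, len(group_tags), seed)),
    ]
    return Pipeline(steps)


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                     group_tags: Sequence[str], seed: int = 0,
                     weighting: bool = True) -> Pipeline:
    """Fit the full preprocessing + classifier pipeline; deterministic per seed."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    pipe = build_pipeline(spec, group_tags, seed, weighting=weighting)
    pipe.fit(X, y)
    return pipe


def class_scores(model: Pipeline, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Continuous per-class scores (n_samples, n_classes), column-aligned."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        raw = model.predict_proba(X)
    else:
        raw = model.decision_function(X)
        if raw.ndim == 1:  # binary: decision for classes_[1]
            raw = np.c_[-raw, raw]
    cols = {c: i for i, c in enumerate(clf.classes_)}
    out = np.full((X.shape[0], len(classes)), -np.inf)
    for j, c in enumerate(classes):
        if c in cols:
            out[:, j] = raw[:, cols[c]]
    return out


# ---------------------------------------------------------------------------
# repeated cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    folds: int = 5
    repeats: int = 20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @classmethod
    def from_settings(cls, s: CVSettings) -> "CVPlan":
        return cls(folds=s.folds, repeats=s.repeats, seed=s.seed, stratified=s.stratified)


@dataclass
class ROCResult:
    classes: list
    class_auc: np.ndarray  # (repeats, n_classes)
    macro_auc: np.ndarray  # (repeats,)
    mean_macro_auc: float
    var_macro_auc: float
    curves: list  # per repeat: {class: (fpr, tpr)}


FoldPlan = list[list[tuple[np.ndarray, np.ndarray]]]


def fold_assignments(y: np.ndarray, plan: CVPlan) -> FoldPlan:
    """Reproducible fold indices for every repeat (shared across conditions)."""
    seeds = np.random.SeedSequence(plan.seed).generate_state(plan.repeats) % (2**31)
    folds: FoldPlan = []
    splitter_cls = StratifiedKFold if plan.stratified else KFold
    for r in range(plan.repeats):
        sk = splitter_cls(n_splits=plan.folds, shuffle=True, random_state=int(seeds[r]))
        folds.append([(tr, te) for tr, te in sk.split(np.zeros(len(y)), y)])
    return folds


def cross_validate(
    table: FeatureTable,
    spec: ClassifierSpec,
    plan: CVPlan,
    columns: Sequence[str] | None = None,
    weighting: bool = True,
    folds: FoldPlan | None = None,
    store_curves: bool = False,
    fit_hook: Callable | None = None,
) -> ROCResult:
    """Repeated stratified k-fold CV with pooled one-vs-rest ROC/AUC.

    Per repeat, folds are reshuffled; out-of-fold scores from all k test
    folds are pooled into one ROC per class and a macro AUC.  The mean
    and variance (ddof=1) of the macro AUC across repeats summarize the
    result.  ``fit_hook(repeat, fold, pipeline)`` is called after each
    fold fit (instrumentation, e.g. leakage checks).
    """
    cols = list(columns) if columns is not None else table.feature_columns
    tags = [table.groups[c] for c in cols]
    X = table.matrix(cols)
    y = table.labels
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    if plan.stratified and counts.min() < plan.folds:
        raise ValueError(
            f"class count {counts.min()} below fold count {plan.folds}; cannot stratify"
        )
    if folds is None:
        folds = fold_assignments(y, plan)
    seeds = np.random.SeedSequence((plan.seed, 1)).generate_state(plan.repeats) % (2**31)
    class_auc = np.zeros((plan.repeats, len(classes)))
    curves: list = []
    for r in range(plan.repeats):
        scores = np.zeros((len(y), len(classes)))
        for f, (tr, te) in enumerate(folds[r]):
            model = train_classifier(X[tr], y[tr], spec, tags, seed=int(seeds[r]),
                                     weighting=weighting)
            if fit_hook is not None:
                fit_hook(r, f, model)
            scores[te] = class_scores(model, X[te], classes)
        repeat_curves = {}
        for j, c in enumerate(classes):
            fpr, tpr, auc = roc_curve(scores[:, j], y == c)
            class_auc[r, j] = auc
            if store_curves:
                repeat_curves[c] = (fpr, tpr)
        if store_curves:
            curves.append(repeat_curves)
    macro = class_auc.mean(axis=1)
    var = float(np.var(macro, ddof=1)) if plan.repeats > 1 else 0.0
    logger.info("%s CV: mean macro AUC %.4f, variance %.5f over %d repeats",
                spec.kind, macro.mean(), var, plan.repeats)
    return ROCResult(
        classes=list(classes),
        class_auc=class_auc,
        macro_auc=macro,
        mean_macro_auc=float(macro.mean()),
        var_macro_auc=var,
        curves=curves,
    )


def compare_feature_groups(
    table: FeatureTable,
    spec: ClassifierSpec,
    plan: CVPlan,
) -> dict[str, ROCResult]:
    """Per-category CV plus the weighted combination, on shared folds.

    Conditions: texture, FPS, holographic, polarization (each restricted
    to its own columns, unweighted) and 'combined' (all columns with the
    spec's category ratio).  Shared fold assignments make the across-
    condition comparison paired per repeat.
    """
    y = table.labels
    folds = fold_assignments(y, plan)
    results: dict[str, ROCResult] = {}
    for cat in CATEGORY_ORDER:
        cols = table.features_in_group(*CATEGORY_GROUPS[cat])
        if not cols:
            raise ValueError(f"no features for category {cat!r}")
        results[cat] = cross_validate(table, spec, plan, columns=cols,
                                      weighting=False, folds=folds)
    results["combined"] = cross_validate(table, spec, plan, weighting=True, folds=folds)
    return results
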