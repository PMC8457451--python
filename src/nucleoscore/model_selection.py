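"""Preprocessing, feature selection and stratified nested cross-validation.

The patient-level 72-feature table is classified with a pipeline of
optional quantile transformation (uniform target) and standard scaling,
optional univariate chi-squared or sequential-forward feature selection
(k in [1, 25]), and one of six classifiers (SVC, KNN, GNB, DT, LogReg, RF).
Generalization is estimated by nested cross-validation: 5 stratified outer
folds; inside each outer-training portion, preprocessors and the selector
are fitted once and only the classifier hyperparameters are tuned by a
4-fold stratified inner grid search.  The preprocessing / selector /
classifier combination itself is fixed by the configuration, not tuned
inside the nested loop.

The learnable pieces are scikit-learn estimators: `Chi2Selector` and
`SequentialForwardSelector` are `SelectorMixin` transformers, and
`NestedCVClassifier` is a classifier whose `fit` runs the full nested CV
(report in ``report_``) and refits a final model on all data for
`predict` / `decision_function`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import SelectorMixin, chi2
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    auc as _auc,
    cohen_kappa_score,
    confusion_matrix,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import QuantileTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, validate_data

from nucleoscore.aggregation import PATIENT_FEATURES

__all__ = [
    "Selector",
    "Classifier",
    "PipelineConfig",
    "FoldResult",
    "EvaluationReport",
    "Chi2Selector",
    "SequentialForwardSelector",
    "NestedCVClassifier",
    "derive_seed",
    "fit_preprocessors",
    "select_chi2",
    "select_sfs",
    "nested_cv",
    "metrics",
    "majority_vote",
    "baseline_config",
    "DEFAULT_GRIDS",
]

POSITIVE_CLASS = "PTC"
NEGATIVE_CLASS = "nonPTC"


class Selector(str, enum.Enum):
    NONE = "none"
    CHI2 = "chi2"
    SFS = "sfs"


class Classifier(str, enum.Enum):
    SVC = "svc"
    KNN = "knn"
    GNB = "gnb"
    DT = "dt"
    LOGREG = "logreg"
    RF = "rf"


#: Candidate hyperparameter grids searched in the inner cross-validation.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svc": {
        "C": [0.1, 1, 10, 100],
        "kernel": ["rbf", "linear"],
        "gamma": ["scale", 0.01, 0.001],
    },
    "knn": {"n_neighbors": [3, 5, 7, 11], "weights": ["uniform", "distance"]},
    "gnb": {},
    "dt": {"max_depth": [3, 5, 10, None]},
    "logreg": {"C": [0.01, 0.1, 1, 10]},
    "rf": {"n_estimators": [100, 300], "max_depth": [5, None]},
}


def derive_seed(master: int, stream: int) -> int:
    """Derive an independent 31-bit child seed (splitmix64-style mixing)."""
    z = (master + (stream + 1) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return int((z ^ (z >> 31)) % (2**31))


@dataclass
class PipelineConfig:
    """Fixed (not nested-CV-tuned) choices of the classification pipeline."""

    quantile_transform: bool = True
    standard_scale: bool = True
    selector: Selector = Selector.NONE
    k_features: int = 22
    classifier: Classifier = Classifier.SVC
    hyper_grid: dict[str, list] | None = None  # None -> DEFAULT_GRIDS entry
    outer_folds: int = 5
    inner_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.selector = Selector(self.selector)
        self.classifier = Classifier(self.classifier)
        if self.selector is not Selector.NONE and not 1 <= self.k_features <= 25:
            raise ValueError("k_features must be in [1, 25]")

    def grid(self) -> dict[str, list]:
        if self.hyper_grid is not None:
            return self.hyper_grid
        return DEFAULT_GRIDS[self.classifier.value]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selector"] = self.selector.value
        d["classifier"] = self.classifier.value
        return d


def baseline_config(seed: int = 0) -> PipelineConfig:
    """Untuned reference configuration: default-hyperparameter SVC.

    Standard scaling on, quantile transform off, no feature selection, and
    a grid of size one so the inner loop degenerates to a plain fit.  The
    outer splits are identical to a tuned run with the same seed, making
    the comparison a like-for-like cross-validation.
    """
    return PipelineConfig(
        quantile_transform=False,
        standard_scale=True,
        selector=Selector.NONE,
        classifier=Classifier.SVC,
        hyper_grid={},
        seed=seed,
    )


def make_classifier(kind: Classifier, seed: int) -> BaseEstimator:
    if kind is Classifier.SVC:
        return SVC(random_state=seed)
    if kind is Classifier.KNN:
        return KNeighborsClassifier()
    if kind is Classifier.GNB:
        return GaussianNB()
    if kind is Classifier.DT:
        return DecisionTreeClassifier(random_state=seed)
    if kind is Classifier.LOGREG:
        return LogisticRegression(max_iter=5000, random_state=seed)
    if kind is Classifier.RF:
        return RandomForestClassifier(random_state=seed)
    raise ValueError(kind)


def fit_preprocessors(train: np.ndarray, cfg: PipelineConfig) -> Pipeline:
    """Fit the preprocessing stack on training data only.

    Median imputation (NA policy) is always first; then the optional
    quantile transform (uniform target, n_quantiles = min(1000, n_train)),
    then optional standard scaling.  Both off yields (after imputation) an
    identity transform.
    """
    steps: list[tuple[str, Any]] = [("impute", SimpleImputer(strategy="median"))]
    if cfg.quantile_transform:
        steps.append(
            (
                "quantile",
                QuantileTransformer(
                    output_distribution="uniform",
                    n_quantiles=min(1000, len(train)),
                    random_state=derive_seed(cfg.seed, 101),
                ),
            )
        )
    if cfg.standard_scale:
        steps.append(("scale", StandardScaler()))
    pipe = Pipeline(steps)
    pipe.fit(np.asarray(train, dtype=np.float64))
    return pipe


class Chi2Selector(SelectorMixin, BaseEstimator):
    """Top-k univariate chi-squared feature selection.

    The chi2 statistic requires non-negative inputs; with
    ``scale_nonneg=True`` (default) each feature is min-max mapped to
    [0, 1] on the training data for scoring only — the selected columns of
    the untouched input are what downstream estimators see.
    """

    def __init__(self, k: int = 22, scale_nonneg: bool = True):
        self.k = k
        self.scale_nonneg = scale_nonneg

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k={self.k} not in [1, {X.shape[1]}]")
        Xs = X
        if self.scale_nonneg:
            lo, hi = X.min(axis=0), X.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            Xs = (X - lo) / span
        elif (X < 0).any():
            raise ValueError(
                "chi2 selection needs non-negative features; "
                "enable scale_nonneg to min-max map them for scoring"
            )
        scores, _ = chi2(Xs, y)
        scores = np.nan_to_num(scores, nan=0.0)
        self.scores_ = scores
        order = np.argsort(-scores, kind="stable")  # ties: canonical order
        top = np.sort(order[: self.k])
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[top] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class SequentialForwardSelector(SelectorMixin, BaseEstimator):
    """Greedy forward feature selection scored by inner cross-validation.

    Starting from the empty set, repeatedly adds the feature whose addition
    maximizes the cross-validated accuracy of ``estimator``; ties are
    broken by canonical (column) order, so selected sets are nested across
    k.  Wrapper-based counterpart to :class:`Chi2Selector`.
    """

    def __init__(self, estimator=None, k: int = 22, cv: int = 4, random_state: int = 0):
        self.estimator = estimator
        self.k = k
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k={self.k} not in [1, {X.shape[1]}]")
        est = self.estimator if self.estimator is not None else SVC(random_state=0)
        splitter = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        selected: list[int] = []
        remaining = list(range(X.shape[1]))
        history: list[float] = []
        for _ in range(self.k):
            best_score, best_j = -np.inf, None
            for j in remaining:  # canonical order -> first max wins ties
                cols = selected + [j]
                score = cross_val_score(
                    clone(est), X[:, cols], y, cv=splitter, scoring="accuracy"
                ).mean()
                if score > best_score + 1e-12:
                    best_score, best_j = score, j
            selected.append(best_j)
            remaining.remove(best_j)
            history.append(best_score)
        self.selected_order_ = list(selected)
        self.score_history_ = history
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[selected] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_chi2(X: pd.DataFrame, y, k: int) -> list[str]:
    """Names of the k features with largest chi2 statistic against class."""
    sel = Chi2Selector(k=k).fit(X.to_numpy(dtype=np.float64), np.asarray(y))
    return [c for c, keep in zip(X.columns, sel.support_) if keep]


def select_sfs(
    X: pd.DataFrame, y, k: int, base_classifier=None, cv: int = 4, seed: int = 0
) -> list[str]:
    """Names of k features chosen by greedy sequential forward selection."""
    sel = SequentialForwardSelector(
        estimator=base_classifier, k=k, cv=cv, random_state=seed
    ).fit(X.to_numpy(dtype=np.float64), np.asarray(y))
    return [X.columns[j] for j in sel.selected_order_]


# ---------------------------------------------------------------------------
# metrics


def _decision_scores(model, X) -> np.ndarray:
    """Monotone score for the positive class: signed margin or probability."""
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=np.float64)
    proba = model.predict_proba(X)
    pos = list(model.classes_).index(1)
    return np.asarray(proba[:, pos], dtype=np.float64)


def metrics(y_true, y_pred, scores=None) -> dict:
    """Accuracy, Cohen's kappa, 2x2 confusion matrix, ROC points and AUC.

    Labels are 0 (non-PTC-like) / 1 (PTC-like); a PTC-like sample
    classified PTC-like is a true positive.  With a single-class truth,
    kappa and AUC are undefined (NA).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out: dict[str, Any] = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "confusion": confusion_matrix(y_true, y_pred, labels=[0, 1]),
    }
    if np.unique(y_true).size < 2:
        out["kappa"] = float("nan")
        out["roc_points"] = None
        out["auc"] = float("nan")
        return out
    out["kappa"] = float(cohen_kappa_score(y_true, y_pred))
    if scores is not None:
        fpr, tpr, _ = roc_curve(y_true, np.asarray(scores), pos_label=1)
        out["roc_points"] = list(zip(fpr.tolist(), tpr.tolist()))
        out["auc"] = float(_auc(fpr, tpr))
    else:
        out["roc_points"] = None
        out["auc"] = float("nan")
    return out


def majority_vote(per_image_predictions: Sequence, true_class):
    """Patient-level class from per-image predictions, pessimistic on ties.

    The majority class wins; on an exact 50-50 split the WRONG class (the
    one opposite the ground truth) is assumed.
    """
    preds = list(per_image_predictions)
    if not preds:
        raise ValueError("need at least one prediction")
    classes, counts = np.unique(preds, return_counts=True)
    if classes.size == 1:
        return classes[0]
    top = counts.max()
    winners = classes[counts == top]
    if winners.size > 1:  # exact tie
        wrong = [c for c in winners if c != true_class]
        return wrong[0]
    return winners[0]


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class FoldResult:
    fold_index: int
    test_patient_ids: list[str]
    y_true: list[int]
    y_pred: list[int]
    scores: list[float]
    accuracy: float
    kappa: float
    confusion: np.ndarray
    roc_points: list | None
    auc: float
    chosen_hyperparams: dict
    chosen_features: list[str]
    validation_accuracy: float
    training_accuracy: float


@dataclass
class EvaluationReport:
    folds: list[FoldResult]
    pooled_accuracy: float
    pooled_kappa: float
    pooled_confusion: np.ndarray
    auc_mean: float
    auc_std: float
    validation_accuracy: float
    training_accuracy: float
    outer_folds: int
    inner_folds: int
    hyperparameter_optimization: bool
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pooled_accuracy": self.pooled_accuracy,
            "pooled_kappa": self.pooled_kappa,
            "pooled_confusion": self.pooled_confusion.tolist(),
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "validation_accuracy": self.validation_accuracy,
            "training_accuracy": self.training_accuracy,
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "hyperparameter_optimization": self.hyperparameter_optimization,
            "config": self.config,
            "folds": [
                {
                    "fold_index": f.fold_index,
                    "test_patient_ids": f.test_patient_ids,
                    "y_true": f.y_true,
                    "y_pred": f.y_pred,
                    "scores": f.scores,
                    "accuracy": f.accuracy,
                    "kappa": f.kappa,
                    "confusion": f.confusion.tolist(),
                    "roc_points": f.roc_points,
                    "auc": f.auc,
                    "chosen_hyperparams": {
                        k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                        for k, v in f.chosen_hyperparams.items()
                    },
                    "chosen_features": f.chosen_features,
                    "validation_accuracy": f.validation_accuracy,
                    "training_accuracy": f.training_accuracy,
                }
                for f in self.folds
            ],
        }


class NestedCVClassifier(ClassifierMixin, BaseEstimator):
    """Nested cross-validated classifier over patient feature tables.

    ``fit`` estimates generalization by stratified nested CV (report in
    ``report_``) and then refits the full pipeline — preprocessors,
    selector and inner-CV-tuned classifier — on all data, so the fitted
    object predicts like the deployed model.
    """

    def __init__(
        self,
        quantile_transform: bool = True,
        standard_scale: bool = True,
        selector: str = "none",
        k_features: int = 22,
        classifier: str = "svc",
        hyper_grid: dict | None = None,
        outer_folds: int = 5,
        inner_folds: int = 4,
        seed: int = 0,
    ):
        self.quantile_transform = quantile_transform
        self.standard_scale = standard_scale
        self.selector = selector
        self.k_features = k_features
        self.classifier = classifier
        self.hyper_grid = hyper_grid
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            quantile_transform=self.quantile_transform,
            standard_scale=self.standard_scale,
            selector=Selector(self.selector),
            k_features=self.k_features,
            classifier=Classifier(self.classifier),
            hyper_grid=self.hyper_grid,
            outer_folds=self.outer_folds,
            inner_folds=self.inner_folds,
            seed=self.seed,
        )

    def fit(self, X, y, patient_ids=None, feature_names=None):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=np.float64)
        X = validate_data(self, X, ensure_all_finite="allow-nan")
        y01, self._class_values_ = _encode_labels(y)
        self.classes_ = np.unique(y01)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        if patient_ids is None:
            patient_ids = [str(i) for i in range(len(y01))]
        self.report_ = _run_nested_cv(X, y01, list(patient_ids), feature_names, cfg)
        self._final_ = _fit_fold_model(X, y01, cfg, fold_seed=derive_seed(cfg.seed, 999))
        self.feature_names_ = feature_names
        return self

    def predict(self, X):
        check_is_fitted(self, "_final_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=np.float64)
        pre, sel_mask, model = self._final_[:3]
        Xp = pre.transform(X)
        return model.predict(Xp[:, sel_mask])

    def decision_function(self, X):
        check_is_fitted(self, "_final_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=np.float64)
        pre, sel_mask, model = self._final_[:3]
        Xp = pre.transform(X)
        return _decision_scores(model, Xp[:, sel_mask])


def _encode_labels(y) -> tuple[np.ndarray, list]:
    """Map labels to {0, 1} with the PTC-like class as 1."""
    y = np.asarray(y)
    uniq = list(np.unique(y))
    if set(uniq) <= {0, 1}:
        return y.astype(int), [0, 1]
    if POSITIVE_CLASS in uniq:
        return (y == POSITIVE_CLASS).astype(int), [NEGATIVE_CLASS, POSITIVE_CLASS]
    # generic binary: second sorted value is positive
    if len(uniq) != 2:
        raise ValueError(f"need binary labels, got {uniq}")
    return (y == uniq[1]).astype(int), uniq


def _fit_fold_model(Xtr, ytr, cfg: PipelineConfig, fold_seed: int):
    """Fit preprocessors + selector on training data, tune the classifier.

    Returns (preprocessor, support mask, fitted model, chosen params,
    validation accuracy, selected feature indices in chosen order).
    """
    pre = fit_preprocessors(Xtr, cfg)
    Xp = pre.transform(Xtr)
    order: list[int]
    if cfg.selector is Selector.NONE:
        mask = np.ones(Xp.shape[1], dtype=bool)
        order = list(range(Xp.shape[1]))
    elif cfg.selector is Selector.CHI2:
        sel = Chi2Selector(k=cfg.k_features).fit(Xp, ytr)
        mask = sel.support_
        order = list(np.flatnonzero(mask))
    else:
        sel = SequentialForwardSelector(
            estimator=make_classifier(cfg.classifier, derive_seed(fold_seed, 7)),
            k=cfg.k_features,
            cv=cfg.inner_folds,
            random_state=derive_seed(fold_seed, 11),
        ).fit(Xp, ytr)
        mask = sel.support_
        order = sel.selected_order_
    Xsel = Xp[:, mask]
    base = make_classifier(cfg.classifier, derive_seed(fold_seed, 13))
    grid = cfg.grid()
    inner = StratifiedKFold(
        n_splits=cfg.inner_folds, shuffle=True, random_state=derive_seed(fold_seed, 17)
    )
    if grid:
        search = GridSearchCV(base, grid, scoring="accuracy", cv=inner, refit=True)
        search.fit(Xsel, ytr)
        model = search.best_estimator_
        chosen = dict(search.best_params_)
        val_acc = float(search.best_score_)
    else:
        model = base.fit(Xsel, ytr)
        chosen = {}
        val_acc = float(cross_val_score(clone(base), Xsel, ytr, cv=inner).mean())
    return pre, mask, model, chosen, val_acc, order


def _run_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: list[str],
    feature_names: list[str],
    cfg: PipelineConfig,
) -> EvaluationReport:
    counts = np.bincount(y)
    if counts.min() < cfg.outer_folds:
        raise ValueError(
            f"need >= {cfg.outer_folds} patients per class for stratified "
            f"outer folds, got {counts.tolist()}"
        )
    outer = StratifiedKFold(
        n_splits=cfg.outer_folds, shuffle=True, random_state=derive_seed(cfg.seed, 1)
    )
    folds: list[FoldResult] = []
    all_true: list[int] = []
    all_pred: list[int] = []
    for fold_i, (tr, te) in enumerate(outer.split(X, y)):
        fold_seed = derive_seed(cfg.seed, 1000 + fold_i)
        pre, mask, model, chosen, val_acc, order = _fit_fold_model(
            X[tr], y[tr], cfg, fold_seed
        )
        Xte = pre.transform(X[te])[:, mask]
        y_pred = model.predict(Xte)
        scores = _decision_scores(model, Xte)
        Xtr_sel = pre.transform(X[tr])[:, mask]
        train_acc = float(accuracy_score(y[tr], model.predict(Xtr_sel)))
        m = metrics(y[te], y_pred, scores)
        folds.append(
            FoldResult(
                fold_index=fold_i,
                test_patient_ids=[patient_ids[i] for i in te],
                y_true=[int(v) for v in y[te]],
                y_pred=[int(v) for v in y_pred],
                scores=[float(s) for s in scores],
                accuracy=m["accuracy"],
                kappa=m["kappa"],
                confusion=m["confusion"],
                roc_points=m["roc_points"],
                auc=m["auc"],
                chosen_hyperparams=chosen,
                chosen_features=[feature_names[j] for j in order],
                validation_accuracy=val_acc,
                training_accuracy=train_acc,
            )
        )
        all_true.extend(int(v) for v in y[te])
        all_pred.extend(int(v) for v in y_pred)
    pooled = metrics(all_true, all_pred)
    aucs = np.array([f.auc for f in folds], dtype=np.float64)
    aucs = aucs[np.isfinite(aucs)]
    return EvaluationReport(
        folds=folds,
        pooled_accuracy=pooled["accuracy"],
        pooled_kappa=pooled["kappa"],
        pooled_confusion=pooled["confusion"],
        auc_mean=float(aucs.mean()) if aucs.size else float("nan"),
        auc_std=float(aucs.std()) if aucs.size else float("nan"),
        validation_accuracy=float(np.mean([f.validation_accuracy for f in folds])),
        training_accuracy=float(np.mean([f.training_accuracy for f in folds])),
        outer_folds=cfg.outer_folds,
        inner_folds=cfg.inner_folds,
        hyperparameter_optimization=bool(cfg.grid()),
        config=cfg.to_dict(),
    )


def nested_cv(patients: pd.DataFrame, cfg: PipelineConfig) -> EvaluationReport:
    """Run the nested cross-validation on a patient feature table.

    The table must carry ``patient_id``, ``class_label`` and the 72
    aggregate features (extra metadata columns are ignored).
    """
    feature_cols = [c for c in PATIENT_FEATURES if c in patients.columns]
    if not feature_cols:  # permit arbitrary feature tables (tests, canaries)
        feature_cols = [
            c
            for c in patients.columns
            if c not in ("patient_id", "class_label", "n_nuclei")
        ]
    clf = NestedCVClassifier(
        quantile_transform=cfg.quantile_transform,
        standard_scale=cfg.standard_scale,
        selector=cfg.selector.value,
        k_features=cfg.k_features,
        classifier=cfg.classifier.value,
        hyper_grid=cfg.hyper_grid,
        outer_folds=cfg.outer_folds,
        inner_folds=cfg.inner_folds,
        seed=cfg.seed,
    )
    clf.fit(
        patients[feature_cols],
        patients["class_label"].to_numpy(),
        patient_ids=list(patients["patient_id"].astype(str)),
        feature_names=feature_cols,
    )
    return clf.report_
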