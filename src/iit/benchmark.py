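"""Inductive benchmarking: nested-preprocessing cross-validated classification.

Three classifier families (random forest, gradient boosting, L2 logistic
regression) are evaluated on the 3-way CN/PD/AD task and the binary PD/AD
task under stratified 5-fold cross-validation repeated over 10 seeds.
Median imputation and z-scoring are fit inside each training fold (an
sklearn Pipeline under GridSearchCV), so no statistic of the held-out fold
leaks into preprocessing or model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import FeatureMatrix, FoldPlan

__all__ = [
    "ModelSpec",
    "CVResult",
    "default_specs",
    "build_pipeline",
    "run_cv_benchmark",
    "compute_metrics",
    "average_confusion_matrix",
]

FAMILIES = ("random_forest", "gradient_boosting", "logistic_l2")

# fixed, family-defining settings: 500 balanced trees for the forest,
# stochastic 0.8 subsampling for boosting, an L2 penalty for the linear model
_FIXED_DEFAULTS = {
    "random_forest": {"n_estimators": 500, "class_weight": "balanced"},
    "gradient_boosting": {"subsample": 0.8, "n_estimators": 300},
    "logistic_l2": {"max_iter": 5000},  # sklearn's default penalty is already L2
}

# small, honest search grids; C is tuned for the linear model
_GRID_DEFAULTS = {
    "random_forest": {"max_depth": [None, 8], "min_samples_leaf": [1, 5]},
    "gradient_boosting": {"learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
    "logistic_l2": {"C": [0.01, 0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with its fixed settings and tunable grid."""

    family: str
    fixed: dict = dc_field(default_factory=dict)
    grid: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {FAMILIES}")
        merged = {**_FIXED_DEFAULTS[self.family], **self.fixed}
        object.__setattr__(self, "fixed", merged)
        if not self.grid:
            object.__setattr__(self, "grid", dict(_GRID_DEFAULTS[self.family]))


def default_specs() -> list[ModelSpec]:
    """The three benchmark families with their default settings."""
    return [ModelSpec(family=f) for f in FAMILIES]


def _make_estimator(spec: ModelSpec, seed: int):
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **spec.fixed)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **spec.fixed)
    return LogisticRegression(random_state=seed, **spec.fixed)


def build_pipeline(spec: ModelSpec, seed: int) -> Pipeline:
    """Imputation -> scaling -> classifier, for nesting inside CV folds."""
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", _make_estimator(spec, seed)),
        ]
    )


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    classes: Sequence[str],
) -> tuple[float, float, float]:
    """(accuracy, F1-macro, ROC-AUC) for one held-out fold.

    ``scores`` holds per-class probabilities in ``classes`` order and must be
    row-normalized.  Two classes use the plain binary AUC on the positive
    class; three or more use macro one-vs-rest.  A class absent from both
    truth and prediction contributes an F1 term of 0 with a warning.
    """
    classes = list(classes)
    scores = np.asarray(scores, dtype=float)
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("class scores must be row-normalized to sum to 1")
    acc = accuracy_score(y_true, y_pred)
    absent = [c for c in classes if c not in set(y_true) and c not in set(y_pred)]
    if absent:
        warnings.warn(
            f"class(es) absent from truth and prediction, F1 term 0: {absent}",
            RuntimeWarning,
            stacklevel=2,
        )
    f1 = f1_score(y_true, y_pred, labels=classes, average="macro", zero_division=0)
    if len(classes) == 2:
        auc = roc_auc_score((np.asarray(y_true) == classes[1]).astype(int), scores[:, 1])
    else:
        auc = roc_auc_score(y_true, scores, multi_class="ovr", average="macro", labels=classes)
    return float(acc), float(f1), float(auc)


def average_confusion_matrix(
    matrices: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Entry-wise mean of per-fold confusion matrices, plus row percentages.

    All matrices must share index/column (class) ordering; the row
    percentages are per-true-class shares of the mean counts.
    """
    if not matrices:
        raise ValueError("no confusion matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("confusion matrices have mismatched class sets")
    mean = sum(m.to_numpy(dtype=float) for m in matrices) / len(matrices)
    mean_df = pd.DataFrame(mean, index=first.index, columns=first.columns)
    row_sums = mean_df.sum(axis=1).replace(0, np.nan)
    pct = mean_df.div(row_sums, axis=0) * 100.0
    return mean_df, pct.fillna(0.0)


@dataclass
class CVResult:
    """Cross-validation outcome: fold-averaged metrics and confusion matrices."""

    task: str
    metrics: pd.DataFrame  # index: family; columns: accuracy, f1_macro, roc_auc
    confusion_mean: dict[str, pd.DataFrame]
    confusion_pct: dict[str, pd.DataFrame]
    per_fold: pd.DataFrame  # family, seed, fold, accuracy, f1_macro, roc_auc


def run_cv_benchmark(
    features: FeatureMatrix,
    plan: FoldPlan,
    specs: Optional[Sequence[ModelSpec]] = None,
    task: str = "threeway",
    inner_folds: int = 3,
) -> CVResult:
    """Benchmark classifier families under nested-preprocessing CV.

    For the binary task the caller passes a FeatureMatrix already restricted
    to the PD/AD subjects (``features.subset(["PD", "AD"])``) and a fold plan
    built on those subjects.  For each seed x fold, a grid search with an
    inner stratified ``inner_folds``-fold CV (scored by ROC-AUC) selects
    hyperparameters on the training portion only; metrics are means over all
    seed x fold evaluations.  Deterministic given the plan's seed list.
    """
    if task not in ("threeway", "binary"):
        raise ValueError("task must be 'threeway' or 'binary'")
    if specs is None:
        specs = default_specs()
    y = features.cohort
    if not y.index.equals(plan.labels.index) or not (y == plan.labels).all():
        raise ValueError("fold plan labels do not match the feature matrix cohorts")
    expected = {"binary": {"PD", "AD"}, "threeway": {"CN", "PD", "AD"}}[task]
    if set(y.unique()) != expected:
        raise ValueError(
            f"task {task!r} expects cohorts {sorted(expected)}, found {sorted(y.unique())}"
        )
    classes = sorted(expected)
    X = features.values
    y_arr = np.asarray(y)

    rows = []
    conf_mean: dict[str, pd.DataFrame] = {}
    conf_pct: dict[str, pd.DataFrame] = {}
    for spec in specs:
        fold_mats = []
        for seed in plan.seeds:
            inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
            scoring = "roc_auc" if len(classes) == 2 else "roc_auc_ovr"
            for fold_no, (train_idx, test_idx) in enumerate(plan.iter_splits(seed)):
                y_train = y_arr[train_idx]
                if len(np.unique(y_train)) < 2:
                    raise ValueError("single-class training fold")
                search = GridSearchCV(
                    build_pipeline(spec, seed),
                    param_grid={f"clf__{k}": v for k, v in spec.grid.items()},
                    cv=inner,
                    scoring=scoring,
                    n_jobs=1,
                    refit=True,
                )
                search.fit(X.iloc[train_idx], y_train)
                y_test = y_arr[test_idx]
                proba = search.predict_proba(X.iloc[test_idx])
                # align probability columns with the sorted class list
                order = [list(search.classes_).index(c) for c in classes]
                proba = proba[:, order]
                y_pred = np.asarray(classes)[np.argmax(proba, axis=1)]
                acc, f1, auc = compute_metrics(y_test, y_pred, proba, classes)
                rows.append(
                    {"family": spec.family, "seed": seed, "fold": fold_no,
                     "accuracy": acc, "f1_macro": f1, "roc_auc": auc}
                )
                mat = confusion_matrix(y_test, y_pred, labels=classes)
                fold_mats.append(pd.DataFrame(mat, index=classes, columns=classes))
        conf_mean[spec.family], conf_pct[spec.family] = average_confusion_matrix(fold_mats)

    per_fold = pd.DataFrame(rows)
    metrics = (
        per_fold.groupby("family", sort=False)[["accuracy", "f1_macro", "roc_auc"]]
        .mean()
    )
    return CVResult(
        task=task,
        metrics=metrics,
        confusion_mean=conf_mean,
        confusion_pct=conf_pct,
        per_fold=per_fold,
    )
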