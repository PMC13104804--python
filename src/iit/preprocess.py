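"""Leakage-safe preprocessing: CSII aggregation, imputation, scaling, folds.

The Cumulative Structural Integrity Index (CSII) collapses a subject's
longitudinal volumes for one region into their arithmetic mean over the
available time points — with the default three time points (0, 12, 24
months), CSII = (V0 + V12 + V24) / 3.  The index smooths measurement noise;
it does not model progression rates.

Imputation and standardization are fit-on-train / apply-anywhere objects so
cross-validation can nest them inside each training fold without leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .simulate import CohortTable

__all__ = [
    "FeatureMatrix",
    "FoldPlan",
    "compute_csii",
    "MedianImputer",
    "ZScorer",
    "make_stratified_folds",
    "atrophy_percentage",
]


@dataclass
class FeatureMatrix:
    """Model-ready subject x feature matrix with cohort labels.

    ``values`` rows are subjects, columns are features (one CSII value per
    region, optionally plus a binary ``sex`` column); ``cohort`` and ``sex``
    share the subject index.
    """

    values: pd.DataFrame
    cohort: pd.Series
    sex: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.cohort.index):
            raise ValueError("values and cohort must share the subject index")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def subset(self, cohorts: Iterable[str]) -> "FeatureMatrix":
        keep = self.cohort.isin(list(cohorts))
        return FeatureMatrix(
            values=self.values.loc[keep],
            cohort=self.cohort.loc[keep],
            sex=None if self.sex is None else self.sex.loc[keep],
        )

    def with_sex_feature(self) -> "FeatureMatrix":
        """Append sex as a binary feature (F=0, M=1) for classification."""
        if self.sex is None:
            raise ValueError("no sex labels available")
        values = self.values.copy()
        values["sex"] = (self.sex == "M").astype(float)
        return FeatureMatrix(values=values, cohort=self.cohort, sex=self.sex)


def compute_csii(table: CohortTable) -> FeatureMatrix:
    """Aggregate longitudinal volumes into one CSII value per region.

    Each cell is the arithmetic mean of the *available* time-point volumes;
    a cell with every time point missing stays NaN and is handled by
    downstream imputation.  By construction the index is invariant to
    time-point permutation.
    """
    # mean over the timepoint level, skipping NaNs
    csii = table.volumes.T.groupby(level="region", sort=False).mean().T
    return FeatureMatrix(values=csii, cohort=table.cohort, sex=table.subjects["sex"])


class MedianImputer:
    """Per-feature median imputation, fit on training rows only."""

    def __init__(self) -> None:
        self.medians_: Optional[pd.Series] = None

    def fit(self, train: pd.DataFrame) -> "MedianImputer":
        fully_missing = train.columns[train.isna().all()]
        if len(fully_missing):
            raise ValueError(
                f"feature(s) fully missing in training data: {list(fully_missing)}"
            )
        self.medians_ = train.median(axis=0, skipna=True)
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        if list(data.columns) != list(self.medians_.index):
            raise ValueError("feature set differs from the training feature set")
        return data.fillna(self.medians_)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


class ZScorer:
    """Z-score standardization with the population-SD (ddof=0) convention.

    A zero-variance training feature is scaled by 1 (and centred) with a
    warning, so degenerate synthetic inputs pass through as all-zeros
    rather than crashing the pipeline.
    """

    def __init__(self) -> None:
        self.mean_: Optional[pd.Series] = None
        self.scale_: Optional[pd.Series] = None

    def fit(self, train: pd.DataFrame) -> "ZScorer":
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"zero-variance feature(s) scaled by 1: {list(sd.index[zero])}",
                RuntimeWarning,
                stacklevel=2,
            )
            sd = sd.mask(zero, 1.0)
        self.scale_ = sd
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None or self.scale_ is None:
            raise RuntimeError("scaler is not fitted")
        return (data - self.mean_) / self.scale_

    def inverse_transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None or self.scale_ is None:
            raise RuntimeError("scaler is not fitted")
        return data * self.scale_ + self.mean_

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


@dataclass
class FoldPlan:
    """Stratified k-fold test-index sets for each of several seeds.

    ``test_indices[seed]`` is a list of ``k`` disjoint positional index
    arrays that partition ``0..n-1``; stratification keeps per-fold cohort
    proportions within one subject of the global proportions.
    """

    seeds: list[int]
    k: int
    labels: pd.Series
    test_indices: dict[int, list[np.ndarray]] = field(repr=False, default_factory=dict)

    def iter_splits(self, seed: int):
        """Yield (train_idx, test_idx) pairs for one seed."""
        n = len(self.labels)
        for test in self.test_indices[seed]:
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            yield np.flatnonzero(mask), test


def make_stratified_folds(
    labels: pd.Series, k: int = 5, seeds: Sequence[int] = tuple(range(10))
) -> FoldPlan:
    """Plan stratified k-fold splits for each seed.

    Raises
    ------
    ValueError
        If ``k < 2`` (no held-out data) or any cohort has fewer than ``k``
        members.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    counts = labels.value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"cohort(s) smaller than k={k}: {dict(too_small)}"
        )
    y = np.asarray(labels)
    plan = FoldPlan(seeds=list(seeds), k=k, labels=labels)
    for seed in seeds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        plan.test_indices[seed] = [test for _, test in skf.split(np.zeros(len(y)), y)]
    return plan


def atrophy_percentage(cn_mean: float, group_mean: float) -> float:
    """Percentage atrophy of a disease-group mean relative to the CN baseline.

    Returns ``100 * (cn_mean - group_mean) / cn_mean`` rounded to two
    decimals; negative values denote volumetric expansion.
    """
    if not cn_mean > 0:
        raise ValueError("cn_mean must be strictly positive")
    return round(100.0 * (cn_mean - group_mean) / cn_mean, 2)
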