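"""Transductive anchor discovery: Borda consensus and the IIT score.

Importance Inversion Transfer (IIT) inverts the usual feature-selection
logic.  Three classifier families are trained on the full disease-only
(AD + PD) manifold; each feature's importance rank r_{i,m} (1 = most
discriminative) is averaged across the M = 3 models into a Borda score

    B_i = (1/M) * sum_m r_{i,m},

so *high* B_i marks discriminative neutrality.  The IIT score couples that
neutrality with distributional consistency (Spearman's rho between the AD
and PD value profiles of the feature) and geometric proximity (the
normalized mean difference Delta_i = |mean_AD - mean_PD| / sigma_CN):

    IIT_i = B_i * rho_i / (1 + Delta_i).

The ten highest-scoring features are the candidate structural anchors; the
ten lowest-Borda features are the bifurcation markers that drive AD/PD
separation.  Healthy controls enter only through sigma_CN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .benchmark import ModelSpec, _make_estimator, default_specs
from .preprocess import FeatureMatrix, MedianImputer, ZScorer

__all__ = [
    "ImportanceRanking",
    "AnchorSet",
    "extract_importance",
    "borda_consensus",
    "spearman_consistency",
    "normalized_mean_difference",
    "iit_score",
    "compute_iit_components",
    "select_anchors",
]


@dataclass
class ImportanceRanking:
    """Per-feature importance values and ranks for one fitted model."""

    family: str
    importance: pd.Series
    ranks: pd.Series  # 1 = most discriminative; ties get average ranks


def extract_importance(model, family: str, feature_names: Sequence[str]) -> ImportanceRanking:
    """Importance values and descending ranks from a fitted classifier.

    Tree ensembles contribute impurity-based importances; the linear model
    contributes the absolute standardized coefficient (features must have
    been z-scored before fitting so magnitudes are comparable).
    """
    if family in ("random_forest", "gradient_boosting"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif family == "logistic_l2":
        coef = np.asarray(model.coef_, dtype=float)
        imp = np.abs(coef[0]) if coef.shape[0] == 1 else np.abs(coef).mean(axis=0)
    else:
        raise ValueError(f"unknown model family {family!r}")
    if len(imp) != len(feature_names):
        raise ValueError("importance length does not match feature names")
    if np.all(imp == imp[0]):
        warnings.warn(
            f"{family}: all importances tied; every rank is (p+1)/2",
            RuntimeWarning,
            stacklevel=2,
        )
    ranks = rankdata(-imp, method="average")
    idx = pd.Index(feature_names, name="feature")
    return ImportanceRanking(
        family=family,
        importance=pd.Series(imp, index=idx),
        ranks=pd.Series(ranks, index=idx),
    )


def borda_consensus(rankings: Sequence[ImportanceRanking]) -> pd.Series:
    """Mean importance rank B_i across models (high = neutral)."""
    if not rankings:
        raise ValueError("need at least one ranking")
    base = rankings[0].ranks.index
    for r in rankings[1:]:
        if not r.ranks.index.equals(base):
            raise ValueError("rankings do not share the same feature set")
    return sum(r.ranks for r in rankings) / len(rankings)


def spearman_consistency(
    ad_values: np.ndarray, pd_values: np.ndarray, mode: str = "quantile"
) -> float:
    """Spearman rank correlation between the AD and PD value profiles.

    The cohorts contain different subjects, so the default ``quantile``
    policy sorts both samples ascending and aligns them by quantile,
    interpolating the larger sample down to the smaller size when lengths
    differ.  Two distinct-valued samples of equal size are co-monotone
    after sorting and give exactly 1.  A constant aligned vector makes the
    correlation undefined; rho is then 0 with a warning.
    """
    if mode != "quantile":
        raise ValueError(f"unknown rho mode {mode!r}")
    a = np.sort(np.asarray(ad_values, dtype=float))
    b = np.sort(np.asarray(pd_values, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n = min(a.size, b.size)
    if a.size != n:
        a = np.quantile(a, np.linspace(0.0, 1.0, n))
    if b.size != n:
        b = np.quantile(b, np.linspace(0.0, 1.0, n))
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn(
            "constant aligned sample; Spearman rho undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    if n == 1:
        warnings.warn("single-point samples; rho undefined, returning 0", RuntimeWarning)
        return 0.0
    rho = spearmanr(a, b).statistic
    return float(rho)


def normalized_mean_difference(mean_ad: float, mean_pd: float, sigma_cn: float) -> float:
    """Delta = |mean_AD - mean_PD| / sigma_CN (the mean-difference penalty).

    With sigma_CN = 0: Delta is 0 when the means agree, +inf otherwise
    (driving the downstream score to 0).
    """
    if sigma_cn < 0:
        raise ValueError("sigma_cn must be >= 0")
    diff = abs(mean_ad - mean_pd)
    if sigma_cn == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / sigma_cn


def iit_score(borda, rho, delta):
    """IIT = B * rho / (1 + Delta); vectorized over array-likes."""
    borda = np.asarray(borda, dtype=float)
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    with np.errstate(invalid="ignore"):
        out = borda * rho / (1.0 + delta)
    # B*rho finite over an infinite penalty -> 0 (including the 0 * inf case)
    out = np.where(np.isinf(delta), 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def compute_iit_components(
    features: FeatureMatrix,
    seed: int = 0,
    specs: Optional[Sequence[ModelSpec]] = None,
    normalize_borda: bool = False,
) -> pd.DataFrame:
    """Full per-feature IIT component table on the disease-only manifold.

    ``features`` must contain CN, PD and AD subjects with purely
    neuroanatomical columns (no sex feature).  The three classifier
    families are fitted with their fixed settings on the imputed,
    z-scored AD + PD subjects; CN subjects contribute only sigma_CN
    (sample SD, ddof=1).  Returns a DataFrame indexed by feature with
    columns ``borda, rho, mean_ad, mean_pd, sigma_cn, delta, iit_score``.

    ``normalize_borda`` rescales B from the raw 1..p mean-rank range to
    [0, 1] via (B - 1) / (p - 1) before scoring.
    """
    cohorts = set(features.cohort.unique())
    if not {"PD", "AD"} <= cohorts:
        raise ValueError("feature matrix must contain PD and AD subjects")
    if "CN" not in cohorts:
        raise ValueError("feature matrix must contain CN subjects (for sigma_CN)")
    if specs is None:
        specs = default_specs()

    disease = features.subset(["PD", "AD"])
    X_raw = disease.values
    imputed = MedianImputer().fit_transform(X_raw)
    X = ZScorer().fit_transform(imputed)
    y = np.asarray(disease.cohort)

    rankings = []
    for spec in specs:
        est = _make_estimator(spec, seed)
        est.fit(X, y)
        rankings.append(extract_importance(est, spec.family, list(X.columns)))
    borda = borda_consensus(rankings)
    p = len(borda)
    if normalize_borda and p > 1:
        borda = (borda - 1.0) / (p - 1.0)

    ad_vals = disease.values[np.asarray(disease.cohort == "AD")]
    pd_vals = disease.values[np.asarray(disease.cohort == "PD")]
    cn_vals = features.subset(["CN"]).values

    rows = {}
    for feat in features.feature_names:
        a = ad_vals[feat].dropna().to_numpy()
        b = pd_vals[feat].dropna().to_numpy()
        c = cn_vals[feat].dropna().to_numpy()
        rho = spearman_consistency(a, b)
        mean_ad, mean_pd = float(a.mean()), float(b.mean())
        sigma_cn = float(c.std(ddof=1)) if c.size > 1 else 0.0
        delta = normalized_mean_difference(mean_ad, mean_pd, sigma_cn)
        rows[feat] = {
            "borda": float(borda[feat]),
            "rho": rho,
            "mean_ad": mean_ad,
            "mean_pd": mean_pd,
            "sigma_cn": sigma_cn,
            "delta": delta,
        }
    comp = pd.DataFrame.from_dict(rows, orient="index")
    comp.index.name = "feature"
    comp["iit_score"] = iit_score(comp["borda"], comp["rho"], comp["delta"])
    return comp


@dataclass
class AnchorSet:
    """Top-k anchors by IIT score and k lowest-Borda bifurcation markers."""

    anchors: pd.DataFrame
    bifurcation_markers: pd.DataFrame
    np_before: float
    np_after: float

    @property
    def anchor_names(self) -> list[str]:
        return list(self.anchors.index)

    @property
    def bifurcation_names(self) -> list[str]:
        return list(self.bifurcation_markers.index)


def select_anchors(
    components: pd.DataFrame, k: int = 10, n_subjects: Optional[int] = None
) -> AnchorSet:
    """Select the k highest-IIT anchors and k lowest-Borda bifurcation markers.

    Ties break by ascending feature name for cross-platform reproducibility.
    ``n_subjects`` (total N across cohorts) feeds the reported
    subject-to-feature ratios N/p before and after the reduction; with the
    study-scale N = 303, p = 84 and k = 10 the ratio moves from ~3.6 to 30.3.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    p = len(components)
    if p == 0:
        raise ValueError("no features scored")
    if k > p:
        warnings.warn(
            f"k={k} exceeds feature count p={p}; returning all features",
            RuntimeWarning,
            stacklevel=2,
        )
        k = p
    by_name = components.sort_index()
    anchors = by_name.sort_values("iit_score", ascending=False, kind="stable").head(k)
    bifurc = by_name.sort_values("borda", ascending=True, kind="stable").head(k)
    n = float(n_subjects) if n_subjects is not None else float("nan")
    return AnchorSet(
        anchors=anchors,
        bifurcation_markers=bifurc,
        np_before=n / p,
        np_after=n / k,
    )
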