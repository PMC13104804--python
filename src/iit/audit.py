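"""Nonparametric audit of candidate anchors.

The validation hierarchy per region:

1. Kruskal–Wallis H across the three cohorts (global test);
2. Dunn's post-hoc z-tests on the joint average ranks, Bonferroni-corrected
   over the three cohort pairs;
3. a direct two-sided Mann–Whitney U between AD and PD — the anchor
   criterion: a region whose AD/PD distributions are statistically
   indistinguishable (p >= alpha, default 0.05) is a *master anchor*,
   otherwise a *transition pillar*;
4. Cohen's d (pooled SD, reported unsigned) between AD and PD;
5. bootstrapped per-cohort ensemble means for profiling.

Dunn's test is implemented here directly (z on joint average ranks with tie
correction); it is cross-checked against a permutation oracle in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FeatureMatrix, compute_csii
from .simulate import CohortTable

__all__ = [
    "AuditRecord",
    "BootstrapProfile",
    "kruskal_wallis",
    "dunn_posthoc",
    "ad_pd_indistinguishability",
    "cohens_d",
    "classify_anchor",
    "audit_regions",
    "bootstrap_profiles",
    "paired_region_ttest",
    "MASTER_ANCHOR",
    "TRANSITION_PILLAR",
]

MASTER_ANCHOR = "master_anchor"
TRANSITION_PILLAR = "transition_pillar"


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and its chi-square p-value.

    Degenerate input (every value identical across all groups) returns
    (0.0, 1.0) rather than an undefined statistic.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _joint_rank_variance(pooled: np.ndarray) -> float:
    """Tie-corrected rank variance term of Dunn's z: N(N+1)/12 - T."""
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    return n * (n + 1) / 12.0 - tie_term


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    labels: Optional[Sequence[str]] = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc comparisons on joint average ranks.

    Returns a DataFrame with one row per group pair: z, raw two-sided p,
    and the Bonferroni-adjusted p (times the number of pairs, capped at 1).
    Completely tied data yield z = 0 and p = 1 for every pair.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group must have at least two observations")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    var_term = _joint_rank_variance(pooled)
    n_pairs = len(groups) * (len(groups) - 1) // 2

    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se_sq = var_term * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se_sq <= 0:  # all values identical -> no rank variance
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se_sq)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "z": float(z),
                "p_raw": float(min(p_raw, 1.0)),
                "p_adjusted": float(min(p_raw * n_pairs, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def ad_pd_indistinguishability(
    ad_values: np.ndarray, pd_values: np.ndarray
) -> float:
    """Two-sided Mann–Whitney U p-value for the AD-vs-PD anchor criterion.

    Policy: the exact U distribution when the pooled data are tie-free,
    otherwise the normal approximation with tie and continuity corrections
    (under which two identical samples give exactly p = 1).  The
    approximation is checked against a brute-force enumeration oracle at
    small n in the test suite.
    """
    a = np.asarray(ad_values, dtype=float)
    b = np.asarray(pd_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def cohens_d(ad_values: np.ndarray, pd_values: np.ndarray) -> float:
    """Unsigned Cohen's d between two samples with (n-1)-weighted pooled SD."""
    a = np.asarray(ad_values, dtype=float)
    b = np.asarray(pd_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float(abs(a.mean() - b.mean()) / pooled)


def classify_anchor(p_ad_pd: float, alpha: float = 0.05) -> str:
    """Master anchor iff the AD/PD p-value meets the >= alpha criterion."""
    if not 0 <= p_ad_pd <= 1:
        raise ValueError("p-value must lie in [0, 1]")
    return MASTER_ANCHOR if p_ad_pd >= alpha else TRANSITION_PILLAR


@dataclass
class AuditRecord:
    """Per-region audit: global and pairwise tests, effect size, class."""

    region: str
    h_statistic: float
    p_global: float
    p_cn_pd: float
    p_cn_ad: float
    p_pd_ad: float
    p_ad_pd_direct: float
    effect_size: float
    classification: str


def audit_regions(
    features: FeatureMatrix,
    regions: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the full audit hierarchy over regions of a CN/PD/AD feature matrix.

    Returns a DataFrame indexed by region with the Kruskal–Wallis H and
    p-value, Bonferroni-adjusted Dunn p-values for the three cohort pairs,
    the direct AD-vs-PD Mann–Whitney p, Cohen's d and the
    master-anchor / transition-pillar classification.
    """
    cohorts = set(features.cohort.unique())
    if cohorts != {"CN", "PD", "AD"}:
        raise ValueError("audit expects all three cohorts (CN, PD, AD)")
    if regions is None:
        regions = features.feature_names
    records = []
    for region in regions:
        col = features.values[region]
        by = {
            g: col[np.asarray(features.cohort == g)].dropna().to_numpy()
            for g in ("CN", "PD", "AD")
        }
        h, p_global = kruskal_wallis([by["CN"], by["PD"], by["AD"]])
        dunn = dunn_posthoc(
            [by["CN"], by["PD"], by["AD"]], labels=["CN", "PD", "AD"]
        ).set_index(["group_a", "group_b"])["p_adjusted"]
        p_direct = ad_pd_indistinguishability(by["AD"], by["PD"])
        records.append(
            AuditRecord(
                region=region,
                h_statistic=h,
                p_global=p_global,
                p_cn_pd=float(dunn[("CN", "PD")]),
                p_cn_ad=float(dunn[("CN", "AD")]),
                p_pd_ad=float(dunn[("PD", "AD")]),
                p_ad_pd_direct=p_direct,
                effect_size=cohens_d(by["AD"], by["PD"]),
                classification=classify_anchor(p_direct, alpha=alpha),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("region")
    return df


@dataclass
class BootstrapProfile:
    """Per-cohort bootstrap ensemble of means for one region."""

    region: str
    ensembles: dict[str, np.ndarray]  # cohort -> R resampled means
    means: dict[str, float]
    intervals: dict[str, tuple[float, float]]  # 2.5/97.5 percentile


def bootstrap_profiles(
    data: Union[CohortTable, FeatureMatrix],
    regions: Optional[Sequence[str]] = None,
    n_realizations: int = 10,
    seed: int = 0,
) -> dict[str, BootstrapProfile]:
    """Bootstrapped ensemble means per cohort x region.

    ``data`` is either a CohortTable (CSII is computed first) or a
    FeatureMatrix.  For each cohort and region, ``n_realizations``
    resampled-with-replacement means are drawn from one seeded generator.
    """
    if n_realizations < 2:
        raise ValueError("n_realizations must be >= 2")
    features = compute_csii(data) if isinstance(data, CohortTable) else data
    if regions is None:
        regions = features.feature_names
    rng = np.random.default_rng(seed)
    out: dict[str, BootstrapProfile] = {}
    for region in regions:
        col = features.values[region]
        ensembles, means, intervals = {}, {}, {}
        for g in sorted(features.cohort.unique()):
            vals = col[np.asarray(features.cohort == g)].dropna().to_numpy()
            if vals.size == 0:
                raise ValueError(f"cohort {g!r} is empty for region {region!r}")
            idx = rng.integers(0, vals.size, size=(n_realizations, vals.size))
            boot = vals[idx].mean(axis=1)
            ensembles[g] = boot
            means[g] = float(vals.mean())
            lo, hi = np.percentile(boot, [2.5, 97.5])
            # percentile interval widened to include the point estimate at tiny R
            intervals[g] = (min(float(lo), means[g]), max(float(hi), means[g]))
        out[region] = BootstrapProfile(
            region=region, ensembles=ensembles, means=means, intervals=intervals
        )
    return out


def paired_region_ttest(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Paired two-tailed t-test across regions (pairing unit: region).

    The cohorts contain distinct subjects, so the natural pairing for
    cohort-level comparisons is across per-region summaries.  Raises on
    zero-variance differences (t undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three pairs")
    diff = a - b
    if np.all(diff == diff[0]):
        raise ValueError("zero-variance differences; paired t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
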