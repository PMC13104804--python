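"""Independent test oracles: permutation nulls and brute-force enumerations.

These deliberately avoid the package's code paths: they recompute rank
statistics from first principles so agreement is evidence, not tautology.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def rank_permutation_null(groups, n_perm, seed):
    """Label-permutation null for Kruskal-Wallis H and pairwise Dunn |z|.

    Both statistics depend on the data only through the joint ranks, so
    permuting group labels is equivalent to shuffling the fixed rank
    multiset; that makes the null fully vectorizable.  Returns
    ``(h_null, z_null)`` where ``h_null`` is an (n_perm,) array and
    ``z_null`` maps each group-index pair to an (n_perm,) array of |z|.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    tie_factor = 1.0 - tie_sum / (n**3 - n)

    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = ranks[perm]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        shuffled[:, bounds[i]:bounds[i + 1]].mean(axis=1) for i in range(len(sizes))
    ]
    h = (12.0 / (n * (n + 1))) * sum(
        sizes[i] * mean_ranks[i] ** 2 for i in range(len(sizes))
    ) - 3 * (n + 1)
    h = h / tie_factor
    z = {
        (i, j): np.abs(mean_ranks[i] - mean_ranks[j])
        / np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        for i, j in combinations(range(len(sizes)), 2)
    }
    return h, z


def mannwhitney_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p over all C(n1+n2, n1) labelings."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    mu = n1 * len(b) / 2.0

    def u_stat(group_a_idx):
        ga = pooled[list(group_a_idx)]
        gb = np.delete(pooled, list(group_a_idx))
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_stat(range(n1))
    devs = [abs(u_stat(idx) - mu) for idx in combinations(range(len(pooled)), n1)]
    return float(np.mean([d >= abs(u_obs - mu) - 1e-12 for d in devs]))


def brute_force_borda_and_score(importances, rhos, deltas):
    """Pairwise-comparison ranks -> mean rank -> B * rho / (1 + Delta)."""
    imp = np.asarray(importances, dtype=float)
    m, p = imp.shape
    ranks = np.zeros_like(imp)
    for mi in range(m):
        for i in range(p):
            greater = sum(imp[mi, j] > imp[mi, i] for j in range(p))
            equal = sum(imp[mi, j] == imp[mi, i] for j in range(p))
            ranks[mi, i] = 1 + greater + (equal - 1) / 2.0
    borda = ranks.mean(axis=0)
    return borda, borda * np.asarray(rhos) / (1.0 + np.asarray(deltas))
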