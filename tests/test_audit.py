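from itertools import combinations

import numpy as np
import pytest

from iit import (
    ad_pd_indistinguishability,
    bootstrap_profiles,
    classify_anchor,
    cohens_d,
    dunn_posthoc,
    kruskal_wallis,
    paired_region_ttest,
)
from iit.audit import MASTER_ANCHOR, TRANSITION_PILLAR


from oracles import mannwhitney_enumeration_p, rank_permutation_null


# ----------------------------------------------------------- Kruskal-Wallis

class TestKruskalWallis:
    def test_hand_computed_h(self):
        # closed form: 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1) = 7.2
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    @pytest.mark.parametrize("data_seed", [0, 1, 2])
    def test_chi_square_p_matches_permutation_oracle(self, data_seed):
        rng = np.random.default_rng(data_seed)
        groups = [rng.normal(0, 1, 10), rng.normal(0.6, 1, 10), rng.normal(0.3, 1, 10)]
        h_obs, p_chi = kruskal_wallis(groups)
        h_null, _ = rank_permutation_null(groups, n_perm=100_000, seed=12345)
        p_perm = float(np.mean(h_null >= h_obs - 1e-12))
        assert abs(p_chi - p_perm) <= 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 15), rng.normal(1, 1, 15)]
        h0, p0 = kruskal_wallis(groups)
        for f in (np.exp, lambda x: x**3):
            h1, p1 = kruskal_wallis([f(g) for g in groups])
            assert h1 == pytest.approx(h0)
            assert p1 == pytest.approx(p0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])


# --------------------------------------------------------------------- Dunn

class TestDunn:
    def test_identical_groups_all_adjusted_p_one(self):
        out = dunn_posthoc([[3.0, 3.0, 3.0]] * 3)
        assert (out["p_adjusted"] == 1.0).all()

    def test_shifted_group_detected_identical_pair_spared(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 101)
        groups = [base, base.copy(), rng.normal(30, 1, 101)]
        out = dunn_posthoc(groups, labels=["a", "b", "c"]).set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "p_adjusted"] < 1e-6
        assert out.loc[("b", "c"), "p_adjusted"] < 1e-6
        assert out.loc[("a", "b"), "p_adjusted"] > 0.9

    @pytest.mark.parametrize("data_seed", [0, 1, 2])
    def test_raw_p_matches_permutation_oracle(self, data_seed):
        rng = np.random.default_rng(data_seed)
        groups = [rng.normal(0, 1, 10), rng.normal(0.6, 1, 10), rng.normal(0.3, 1, 10)]
        out = dunn_posthoc(groups)
        _, z_null = rank_permutation_null(groups, n_perm=100_000, seed=12345)
        for row, pair in zip(out.itertuples(), combinations(range(3), 2)):
            p_perm = float(np.mean(z_null[pair] >= abs(row.z) - 1e-12))
            assert abs(row.p_raw - p_perm) <= 0.02

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 8) for _ in range(4)]
        out = dunn_posthoc(groups)
        assert (out["p_adjusted"] <= 1.0).all()
        close = out["p_raw"] * 6 < 1
        np.testing.assert_allclose(
            out.loc[close, "p_adjusted"], out.loc[close, "p_raw"] * 6
        )

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0], [2.0, 3.0]])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 12), rng.normal(0.5, 1, 12), rng.normal(1, 1, 12)]
        p0 = dunn_posthoc(groups)["p_raw"].to_numpy()
        p1 = dunn_posthoc([np.exp(g) for g in groups])["p_raw"].to_numpy()
        np.testing.assert_allclose(p0, p1)


# ------------------------------------------------------------- Mann-Whitney

class TestIndistinguishability:
    def test_identical_samples_give_exactly_one(self):
        assert ad_pd_indistinguishability([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_extreme_separation(self):
        a = np.arange(1, 102, dtype=float)
        b = np.arange(1001, 1102, dtype=float)
        assert ad_pd_indistinguishability(a, b) < 1e-6

    @pytest.mark.parametrize("data_seed", [0, 1, 2, 3])
    def test_small_n_matches_enumeration_oracle(self, data_seed):
        rng = np.random.default_rng(data_seed)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        p = ad_pd_indistinguishability(a, b)
        p_oracle = mannwhitney_enumeration_p(a, b)
        assert abs(p - p_oracle) <= 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        assert ad_pd_indistinguishability(a, b) == pytest.approx(
            ad_pd_indistinguishability(np.exp(a), np.exp(b))
        )


# -------------------------------------------------------------- effect size

class TestCohensD:
    def test_unit_effect(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 5000)
        b = rng.normal(1, 1, 5000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(x, x) == 0.0

    def test_hand_computed_pooled_sd(self):
        a = np.array([1.0, 2.0, 3.0])   # mean 2, var 1
        b = np.array([4.0, 6.0, 8.0])   # mean 6, var 4
        pooled = np.sqrt((2 * 1 + 2 * 4) / 4)
        assert cohens_d(a, b) == pytest.approx(4.0 / pooled)

    def test_reported_unsigned(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, b) == cohens_d(b, a) > 0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([2.0, 2.0], [3.0, 3.0])


# ------------------------------------------------------------ classification

class TestClassifyAnchor:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.1063, MASTER_ANCHOR),      # transverse temporal style invariance
            (0.0000, TRANSITION_PILLAR),  # clear AD/PD divergence
            (0.05, MASTER_ANCHOR),        # boundary: criterion is >=
            (0.0510, MASTER_ANCHOR),
        ],
    )
    def test_criterion(self, p, expected):
        assert classify_anchor(p, alpha=0.05) == expected

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_anchor(1.5)


# ---------------------------------------------------------------- bootstrap

class TestBootstrap:
    def test_seeded_reproducibility(self, gaussian_factory):
        rng = np.random.default_rng(5)
        fm = gaussian_factory(rng, {"CN": [10.0], "PD": [9.0], "AD": [8.0]}, 20)
        a = bootstrap_profiles(fm, n_realizations=10, seed=3)
        b = bootstrap_profiles(fm, n_realizations=10, seed=3)
        for region in a:
            for g in a[region].ensembles:
                np.testing.assert_array_equal(
                    a[region].ensembles[g], b[region].ensembles[g]
                )

    def test_bootstrap_consistency_large_r(self, gaussian_factory):
        rng = np.random.default_rng(6)
        fm = gaussian_factory(rng, {"CN": [10.0], "PD": [9.0], "AD": [8.0]}, 200)
        prof = bootstrap_profiles(fm, n_realizations=2000, seed=0)["f0"]
        for g in ("CN", "PD", "AD"):
            assert abs(prof.ensembles[g].mean() - prof.means[g]) / prof.means[g] < 0.01

    def test_interval_contains_point_estimate(self, gaussian_factory):
        rng = np.random.default_rng(7)
        fm = gaussian_factory(rng, {"CN": [5.0], "PD": [5.0], "AD": [5.0]}, 15)
        for prof in bootstrap_profiles(fm, n_realizations=10, seed=1).values():
            for g, (lo, hi) in prof.intervals.items():
                assert lo <= prof.means[g] <= hi

    def test_single_subject_cohort_degenerate(self, gaussian_factory):
        rng = np.random.default_rng(8)
        fm = gaussian_factory(rng, {"CN": [5.0], "PD": [5.0], "AD": [5.0]}, 1)
        prof = bootstrap_profiles(fm, n_realizations=10, seed=2)["f0"]
        for g, ens in prof.ensembles.items():
            assert np.all(ens == prof.means[g])


# ------------------------------------------------------------------ paired t

class TestPairedTTest:
    def test_hand_computed_t(self):
        # differences (1, 2, 3): mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        t, p = paired_region_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_region_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_offset_detected(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = a + 5 + rng.normal(0, 0.1, 30)
        _, p = paired_region_ttest(a, b)
        assert p < 1e-10
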