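"""Alpha diversity, Bray-Curtis and PERMANOVA."""

import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as sp_braycurtis

from microbiont.diversity import (
    ace,
    bray_curtis,
    bray_curtis_matrix,
    pairwise_permanova,
    permanova,
    shannon,
)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_single_taxon_zero(self):
        assert shannon([42]) == 0.0

    def test_direct_formula(self):
        # [5,5,10]: p = (.25,.25,.5) -> -sum p ln p
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert shannon([5, 5, 10]) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = rng.integers(1, 100, size=rng.integers(2, 20))
            h = shannon(c)
            assert h <= np.log((c > 0).sum()) + 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestAce:
    def test_no_rare_species_equals_observed(self):
        est, fb = ace(np.array([50, 60, 70]))
        assert est == 3.0 and not fb

    def test_no_singletons_no_cv(self):
        est, fb = ace(np.array([2, 2, 2]))
        assert est == pytest.approx(3.0)
        assert not fb

    def test_formula_oracle(self):
        # counts [1,1,2,3,15]: S_abund=1, S_rare=4, N_rare=7, F1=2,
        # C=1-2/7=5/7, sum i(i-1)F_i = 2*1*1 + 3*2*1 = 8
        # gamma2 = max((4/C)*8/(7*6) - 1, 0) = max(0.7466...-1, 0) = 0
        # S_ACE = 1 + 4/C + (2/C)*0 = 1 + 5.6 = 6.6
        est, fb = ace(np.array([1, 1, 2, 3, 15]))
        c = 1 - 2 / 7
        expected = 1 + 4 / c + (2 / c) * max((4 / c) * 8 / 42 - 1, 0)
        assert est == pytest.approx(expected)
        assert not fb

    def test_all_singletons_falls_back_to_chao1(self):
        est, fb = ace(np.array([1, 1, 1]))
        assert fb
        # bias-corrected Chao1: S_obs + F1(F1-1)/(2(F2+1)) = 3 + 3*2/2 = 6
        assert est == pytest.approx(6.0)

    def test_at_least_observed_richness_with_singletons(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            c = rng.integers(1, 30, size=20)
            c[0] = 1
            est, _ = ace(c)
            assert est >= (c > 0).sum() - 1e-9

    @pytest.mark.parametrize("counts", [
        [1, 1, 2, 3, 15],
        [1, 2, 2, 4, 5, 9, 11, 40],
        [1, 1, 1, 2, 6, 7, 8, 10, 12, 20, 33],
        [3, 3, 4, 4, 12, 13],
    ])
    def test_agrees_with_skbio(self, counts):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        ours, fb = ace(np.array(counts))
        assert not fb
        theirs = skbio_alpha.ace(np.array(counts))
        assert ours == pytest.approx(theirs, rel=1e-9)


class TestBrayCurtis:
    def test_identity_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            x = rng.integers(0, 50, size=12).astype(float)
            y = rng.integers(0, 50, size=12).astype(float)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(sp_braycurtis(x, y))

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


def two_cluster_distances(n_per=3):
    n = 2 * n_per
    d = np.ones((n, n))
    d[:n_per, :n_per] = 0.0
    d[n_per:, n_per:] = 0.0
    np.fill_diagonal(d, 0.0)
    labels = ["a"] * n_per + ["b"] * n_per
    return d, np.array(labels)


class TestPermanova:
    def test_partition_identity(self):
        rng = np.random.default_rng(5)
        x = rng.random((12, 4))
        d = bray_curtis_matrix(x)
        labels = np.repeat(["a", "b", "c"], 4)
        res = permanova(d, labels, n_permutations=99, seed=0)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total,
                                                             abs=1e-9)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_perfect_separation_minimal_p(self):
        d, labels = two_cluster_distances(3)
        res = permanova(d, labels, n_permutations=999, seed=1)
        # only permutations preserving the cluster split reach F_obs:
        # C(6,3) = 20 label splits and 2 of them are cluster-respecting,
        # so the exhaustive p is 2/20 = 0.1; Monte-Carlo must agree
        assert res.f_statistic > 1e6 or np.isinf(res.f_statistic)
        exhaustive = 2 / 20
        assert res.p_value == pytest.approx(exhaustive, abs=0.03)

    def test_all_equal_distances_give_unit_f(self):
        # with every off-diagonal distance equal, SS_among = d^2 (g-1)/2 and
        # SS_within = d^2 (n-g)/2, so the pseudo-F is exactly 1 (no signal
        # beyond its null expectation) and the permutation p is maximal
        d = np.ones((8, 8)) - np.eye(8)
        labels = np.repeat(["a", "b"], 4)
        res = permanova(d, labels, n_permutations=99, seed=2)
        assert res.ss_among == pytest.approx(0.5, abs=1e-9)
        assert res.f_statistic == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_singleton_group_error_names_group(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="lonely"):
            permanova(d, np.array(["a", "a", "b", "b", "lonely"]),
                      n_permutations=99)

    def test_zero_distances_error(self):
        d = np.zeros((6, 6))
        with pytest.raises(ValueError, match="F undefined|zero"):
            permanova(d, np.repeat(["a", "b"], 3), n_permutations=99)

    def test_pseudo_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        x = rng.random((15, 5))
        d = bray_curtis_matrix(x)
        labels = np.repeat(["a", "b", "c"], 5)
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d), grouping=list(labels),
            permutations=99)
        assert ours.f_statistic == pytest.approx(theirs["test statistic"],
                                                 rel=1e-9)

    def test_exhaustive_permutation_matches_monte_carlo(self):
        """At n = 6 the permutation distribution can be enumerated; the
        Monte-Carlo p must converge to the exhaustive one."""
        from itertools import permutations as iperm

        rng = np.random.default_rng(7)
        x = rng.random((6, 3))
        d = bray_curtis_matrix(x)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(d, labels, n_permutations=9999, seed=3)
        from microbiont.diversity import _pseudo_f

        codes = (labels == "b").astype(int)
        f_obs = _pseudo_f(d**2, codes, 2)[0]
        stats = [_pseudo_f(d**2, codes[list(p)], 2)[0]
                 for p in iperm(range(6))]
        exhaustive = np.mean([f >= f_obs for f in stats])
        # add-one MC estimate converges to the exhaustive value
        assert res.p_value == pytest.approx(exhaustive, abs=0.02)


class TestPairwisePermanova:
    def test_two_groups_reduce_to_single_test(self):
        d, labels = two_cluster_distances(4)
        pw = pairwise_permanova(d, labels, n_permutations=199, seed=0)
        assert len(pw) == 1
        assert pw[0].p_adjusted == pytest.approx(pw[0].p_value)

    def test_adjusted_monotone_and_geq_raw(self):
        rng = np.random.default_rng(8)
        x = rng.random((18, 4))
        d = bray_curtis_matrix(x)
        labels = np.repeat(["a", "b", "c"], 6)
        pw = pairwise_permanova(d, labels, n_permutations=199, seed=1)
        assert len(pw) == 3
        for r in pw:
            assert r.p_adjusted >= r.p_value - 1e-12
        order = np.argsort([r.p_value for r in pw])
        adj = np.array([r.p_adjusted for r in pw])[order]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_bh_hand_example(self):
        from scipy.stats import false_discovery_control

        adj = false_discovery_control([0.01, 0.02, 0.9], method="bh")
        assert np.allclose(adj, [0.03, 0.03, 0.9])
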