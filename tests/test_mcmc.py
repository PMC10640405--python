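"""Posterior inference machinery: kernel consistency, diagnostics, BF."""

import numpy as np
import pytest
from scipy import stats

import microbiont._kernel as kernel
from microbiont.model import (
    ChainConfig,
    HostRepertoireModel,
    Priors,
    gelman_psrf,
    interpret_bf,
    savage_dickey_bf,
)
from microbiont.repertoire import (
    RepertoireParams,
    history_log_density,
    mean_offdiagonal,
    simulate_history,
)
from microbiont.trees import parse_newick


class TestKernelAgainstReference:
    def test_branch_density_matches_reference(self, four_tip_tree,
                                              asv_distances_3):
        """The numba branch density must reproduce the pure-Python history
        density exactly, branch sums plus root term, beta != 0 included."""
        tree = four_tip_tree
        D = asv_distances_3
        dbar = mean_offdiagonal(D)
        ages = tree.ages
        rng = np.random.default_rng(0)
        for trial in range(15):
            p = RepertoireParams(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                                 rng.uniform(0, 2.5))
            h = simulate_history(tree, D, p, 0.4, seed=trial)
            ref = history_log_density(h, p, D, 0.4)
            n, cap = tree.n_nodes, 256
            ev_t = np.zeros((n, cap))
            ev_a = np.zeros((n, cap), dtype=np.int64)
            ev_g = np.zeros((n, cap), dtype=np.uint8)
            ev_n = np.zeros(n, dtype=np.int64)
            st = h.node_states.astype(np.uint8)
            for b, evs in h.events.items():
                for e, ev in enumerate(evs):
                    ev_t[b, e] = ages[tree.parent[b]] - ev.age
                    ev_a[b, e] = ev.asv
                    ev_g[b, e] = ev.is_gain
                ev_n[b] = len(evs)
            r0 = st[tree.root].sum()
            total = r0 * np.log(0.4) + (D.shape[0] - r0) * np.log(0.6)
            for b in range(n):
                if tree.parent[b] >= 0:
                    total += kernel._branch_log_density(
                        b, st, ev_t, ev_a, ev_g, ev_n,
                        tree.parent.astype(np.int64), tree.branch_length,
                        D, dbar, p.lambda_gain, p.lambda_loss, p.beta, 0)
            assert total == pytest.approx(ref, abs=1e-9)

    def test_bridge_endpoint_and_count_distribution(self):
        """The uniformized bridge hits its endpoints and reproduces the
        closed-form probability of an event-free path."""
        np.random.seed(0)
        g, l, t = 0.7, 0.4, 1.3
        bt = np.empty(64)
        btyp = np.empty(64, dtype=np.uint8)

        def ptrans(x, y, tt):
            mu = g + l
            e = np.exp(-mu * tt)
            p1 = g / mu
            pb = p1 if y == 1 else 1 - p1
            return (e if x == y else 0) + (1 - e) * pb

        for (a, b) in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            none = 0
            reps = 30000
            for _ in range(reps):
                k = kernel._sample_bridge(a, b, t, g, l, bt, btyp)
                cur = a
                for i in range(k):
                    cur = int(btyp[i])
                assert cur == b  # endpoint always honored
                none += (k == 0)
            if a == b:
                rate = g if a == 0 else l
                expected = np.exp(-rate * t) / ptrans(a, b, t)
                se = np.sqrt(expected * (1 - expected) / reps)
                assert none / reps == pytest.approx(expected, abs=5 * se)
            else:
                assert none == 0

    def test_bridge_occupancy_matches_conditional(self):
        """Mean occupancy at an interior time equals the exact conditional
        P(X_s = 1 | endpoints) of the two-state chain."""
        np.random.seed(1)
        g, l, t = 0.7, 0.4, 1.3
        bt = np.empty(64)
        btyp = np.empty(64, dtype=np.uint8)

        def ptrans(x, y, tt):
            mu = g + l
            e = np.exp(-mu * tt)
            p1 = g / mu
            pb = p1 if y == 1 else 1 - p1
            return (e if x == y else 0) + (1 - e) * pb

        smid = 0.6 * t
        for (a, b) in [(0, 0), (0, 1), (1, 1)]:
            occ = 0
            reps = 40000
            for _ in range(reps):
                k = kernel._sample_bridge(a, b, t, g, l, bt, btyp)
                cur = a
                for i in range(k):
                    if bt[i] <= smid:
                        cur = int(btyp[i])
                occ += int(cur)
            expected = ptrans(a, 1, smid) * ptrans(1, b, t - smid) / ptrans(a, b, t)
            se = np.sqrt(expected * (1 - expected) / reps)
            assert occ / reps == pytest.approx(expected, abs=5 * se)


class TestGelmanPsrf:
    def test_iid_same_distribution_near_one(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(size=1000) for _ in range(3)]
        psrf, degen = gelman_psrf(chains)
        assert not degen
        assert 1.0 <= psrf <= 1.1

    def test_constant_equal_chains_flagged_degenerate(self):
        psrf, degen = gelman_psrf([np.ones(50), np.ones(50)])
        assert degen

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(3)
        psrf, degen = gelman_psrf([rng.normal(0, 1, 1000),
                                   rng.normal(10, 1, 1000)])
        assert not degen
        assert psrf > 1.2

    def test_needs_two_chains_of_equal_length(self):
        with pytest.raises(ValueError):
            gelman_psrf([np.ones(100)])
        with pytest.raises(ValueError):
            gelman_psrf([np.zeros(100), np.zeros(50)])


class TestSavageDickey:
    def test_posterior_equal_prior_gives_unit_bf(self):
        rng = np.random.default_rng(4)
        samples = rng.exponential(1.0, size=20000)
        out = savage_dickey_bf(samples, prior_density_at_zero=1.0)
        assert out["bf"] == pytest.approx(1.0, abs=0.15)
        assert not out["is_lower_bound"]

    def test_no_mass_near_zero_reports_lower_bound(self):
        samples = np.full(500, 3.0) + np.random.default_rng(5).normal(
            0, 0.1, 500)
        out = savage_dickey_bf(samples, prior_density_at_zero=1.0)
        assert out["is_lower_bound"]
        assert out["bf"] > 10

    def test_epsilon_reported(self):
        samples = np.random.default_rng(6).exponential(0.5, 1000)
        out = savage_dickey_bf(samples)
        assert out["epsilon"] > 0


class TestInterpretBf:
    @pytest.mark.parametrize("bf,category", [
        (0.5, "no effect"),
        (1.0, "weak/positive"),
        (9.99, "weak/positive"),
        (12.9, "strong"),
        (29.9, "strong"),
        (30.0, "very strong"),
        (150.0, "decisive"),
    ])
    def test_bands(self, bf, category):
        assert interpret_bf(bf) == category

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            interpret_bf(0.0)


@pytest.fixture(scope="module")
def small_fit():
    tree = parse_newick("(A:1,B:1);")
    model = HostRepertoireModel(np.array([[1.0], [0.0]]), tree,
                                np.array([[0.0]]), root_prob=0.5)
    cfg = ChainConfig(cycles=2000, thinning=10, burnin=0.1, chains=2,
                      seed=11)
    return model, cfg, model.fit(cfg, fixed={"beta": 0.0})


class TestFitContracts:
    def test_seeded_determinism_byte_identical(self, small_fit):
        model, cfg, res1 = small_fit
        res2 = model.fit(cfg, fixed={"beta": 0.0})
        assert res1.to_frame().equals(res2.to_frame())

    def test_retained_count_bookkeeping(self, small_fit):
        _, cfg, res = small_fit
        assert res.n_retained == cfg.retained_per_chain * cfg.chains
        assert res.posterior("lambda_gain").size == res.n_retained

    def test_samples_within_prior_support(self, small_fit):
        _, _, res = small_fit
        assert (res.posterior("lambda_gain") > 0).all()
        assert (res.posterior("lambda_loss") > 0).all()
        assert (res.posterior("beta") == 0).all()  # fixed

    def test_tip_probabilities_are_clamped_data(self, small_fit):
        _, _, res = small_fit
        tp = res.tip_probabilities()
        assert tp.loc["A"].iloc[0] == 1.0
        assert tp.loc["B"].iloc[0] == 0.0

    def test_event_rate_accounting(self, small_fit):
        _, _, res = small_fit
        ers = res.event_rate_summary()
        assert ers.total_per_myr == pytest.approx(
            ers.gains_per_myr + ers.losses_per_myr)
        ers2 = res.event_rate_summary("root_age")
        assert ers2.basis_myr == pytest.approx(1.0)

    def test_unrecorded_slice_age_raises_listing_available(self, small_fit):
        _, _, res = small_fit
        with pytest.raises(ValueError, match="available"):
            res.interaction_probabilities(age=0.5)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(cycles=1001, thinning=10)
        with pytest.raises(ValueError):
            ChainConfig(burnin=1.0)

    def test_chain_config_defaults_mirror_protocol(self):
        cfg = ChainConfig()
        assert (cfg.cycles, cfg.thinning, cfg.burnin, cfg.chains) == \
            (150_000, 500, 0.10, 3)


class TestPriorSampling:
    def test_prior_only_mode_reproduces_priors(self):
        """With the likelihood switched off the chain must sample the
        priors; KS on strided subsamples (reducing autocorrelation)."""
        tree = parse_newick("(A:1,B:1);")
        model = HostRepertoireModel(np.array([[1.0], [0.0]]), tree,
                                    np.array([[0.0]]), root_prob=0.5,
                                    priors=Priors())
        res = model.fit(ChainConfig(cycles=120000, thinning=30, burnin=0.1,
                                    chains=2, seed=21), prior_only=True)
        for name, scale in (("lambda_gain", 0.1), ("lambda_loss", 0.1),
                            ("beta", 1.0)):
            s = res.posterior(name)[::8]
            ks = stats.kstest(s, "expon", args=(0, scale))
            assert ks.pvalue > 0.01, (name, ks.pvalue)

    def test_bf_at_no_data_is_near_one(self):
        tree = parse_newick("(A:1,B:1);")
        model = HostRepertoireModel(np.array([[1.0], [0.0]]), tree,
                                    np.array([[0.0]]), root_prob=0.5)
        res = model.fit(ChainConfig(cycles=100000, thinning=20, burnin=0.1,
                                    chains=2, seed=22), prior_only=True)
        out = res.savage_dickey_bf()
        assert out["bf"] == pytest.approx(1.0, abs=0.35)
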