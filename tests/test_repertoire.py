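"""The gain/loss process: rates, simulation, densities, exact oracles."""

import numpy as np
import pytest

from microbiont.repertoire import (
    RepertoireParams,
    exact_tip_likelihood,
    gain_rate,
    history_log_density,
    independent_pruning_loglik,
    joint_tip_pattern_distribution,
    mean_offdiagonal,
    simulate_history,
)
from microbiont.trees import parse_newick


class TestGainRate:
    def test_beta_zero_is_neutral(self, asv_distances_3):
        p = RepertoireParams(0.7, 0.3, 0.0)
        assert gain_rate(0, [1], p, asv_distances_3) == pytest.approx(0.7)

    def test_empty_repertoire_fallback(self, asv_distances_3):
        p = RepertoireParams(0.7, 0.3, 2.0)
        assert gain_rate(0, [], p, asv_distances_3) == pytest.approx(0.7)

    def test_distance_modifier_plugin(self):
        # d(j,R) = dbar/2 with beta=1 doubles the gain rate
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        dbar = mean_offdiagonal(d)
        p = RepertoireParams(0.5, 0.3, 1.0)
        # choose repertoire {1}: d(0, {1}) = 1 = dbar/2 (dbar = 2)
        assert dbar == pytest.approx(2.0)
        assert gain_rate(0, [1], p, d) == pytest.approx(1.0)

    def test_gain_of_present_asv_is_contract_violation(self, asv_distances_3):
        p = RepertoireParams(0.5, 0.3, 1.0)
        with pytest.raises(ValueError):
            gain_rate(1, [0, 1], p, asv_distances_3)

    def test_scale_invariance_of_modifier(self, asv_distances_3):
        """Multiplying all ASV distances by c leaves the rate unchanged."""
        p = RepertoireParams(0.5, 0.3, 1.7)
        for c in (0.1, 3.0, 42.0):
            assert gain_rate(0, [1, 2], p, asv_distances_3) == pytest.approx(
                gain_rate(0, [1, 2], p, c * asv_distances_3))

    def test_min_aggregation_option(self, asv_distances_3):
        p = RepertoireParams(0.5, 0.3, 1.0)
        dbar = mean_offdiagonal(asv_distances_3)
        expected = 0.5 * (dbar / 0.3)
        assert gain_rate(0, [1, 2], p, asv_distances_3,
                         agg="min") == pytest.approx(expected)


class TestSimulateHistory:
    def test_frozen_process_has_no_events(self, three_tip_tree,
                                          asv_distances_3):
        p = RepertoireParams(0.0, 0.0, 0.0)
        h = simulate_history(three_tip_tree, asv_distances_3, p, 0.5, seed=0)
        h.validate()
        assert h.event_counts() == (0, 0)
        root = h.node_states[three_tip_tree.root]
        for tip in three_tip_tree.tip_indices:
            assert np.array_equal(h.node_states[tip], root)

    def test_single_branch_matches_two_state_closed_form(self):
        """Tip presence probability on one branch equals the analytic
        transition probability of the 2-state chain."""
        tree = parse_newick("(A:1.5,B:0.0001);")
        g, l, t = 0.6, 0.4, 1.5
        p = RepertoireParams(g, l, 0.0)
        D = np.array([[0.0]])
        hits = 0
        reps = 4000
        for rep in range(reps):
            h = simulate_history(tree, D, p, root_prob=0.0, seed=rep)
            a_row = tree.tip_labels.index("A")
            hits += h.tip_matrix()[a_row, 0]
        mu = g + l
        expected = g / mu * (1 - np.exp(-mu * t))  # P(0 -> 1 in t)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert hits / reps == pytest.approx(expected, abs=4 * se)

    def test_deterministic_given_seed(self, three_tip_tree, asv_distances_3):
        p = RepertoireParams(0.4, 0.3, 1.0)
        h1 = simulate_history(three_tip_tree, asv_distances_3, p, 0.5, seed=9)
        h2 = simulate_history(three_tip_tree, asv_distances_3, p, 0.5, seed=9)
        assert np.array_equal(h1.node_states, h2.node_states)
        assert h1.events == h2.events

    def test_histories_satisfy_invariants(self, four_tip_tree,
                                          asv_distances_3):
        for seed in range(10):
            p = RepertoireParams(0.5, 0.5, 1.5)
            h = simulate_history(four_tip_tree, asv_distances_3, p, 0.4,
                                 seed=seed)
            h.validate()  # raises on any inconsistency


class TestHistoryLogDensity:
    def test_single_segment_closed_form(self):
        """No events, one ASV absent everywhere: log(1-pi) - lambda_gain*t
        per branch."""
        tree = parse_newick("(A:2.0,B:1.0);")
        p = RepertoireParams(0.3, 0.7, 0.0)
        h = simulate_history(tree, np.array([[0.0]]),
                             RepertoireParams(0.0, 0.0, 0.0), 0.0, seed=0)
        ld = history_log_density(h, p, np.array([[0.0]]), root_prob=0.25)
        assert ld == pytest.approx(np.log(0.75) - 0.3 * 3.0)

    def test_density_of_simulated_history_is_finite(self, four_tip_tree,
                                                    asv_distances_3):
        p = RepertoireParams(0.6, 0.4, 1.2)
        for seed in range(5):
            h = simulate_history(four_tip_tree, asv_distances_3, p, 0.5,
                                 seed=seed)
            assert np.isfinite(history_log_density(h, p, asv_distances_3, 0.5))

    def test_inconsistent_history_identified(self, three_tip_tree,
                                             asv_distances_3):
        from microbiont.repertoire import Event

        p = RepertoireParams(0.5, 0.5, 0.0)
        h = simulate_history(three_tip_tree, asv_distances_3,
                             RepertoireParams(0, 0, 0), 0.0, seed=0)
        # inject a loss of an absent ASV
        branch = three_tip_tree.tip_indices[0]
        h.events[branch] = [Event(age=0.5, asv=0, is_gain=False)]
        with pytest.raises(ValueError, match="branch"):
            history_log_density(h, p, asv_distances_3, 0.5)

    def test_monte_carlo_average_density_matches_transition_probability(self):
        """exp(path density) integrated over simulated bridge realizations:
        the empirical mean of the density ratio against the simulating
        parameters is 1 (importance-sampling identity)."""
        tree = parse_newick("(A:1.0,B:0.0001);")
        D = np.array([[0.0]])
        p_sim = RepertoireParams(0.5, 0.5, 0.0)
        p_alt = RepertoireParams(0.8, 0.3, 0.0)
        ratios = []
        for seed in range(3000):
            h = simulate_history(tree, D, p_sim, 0.5, seed=seed)
            num = history_log_density(h, p_alt, D, 0.5, validate=False)
            den = history_log_density(h, p_sim, D, 0.5, validate=False)
            ratios.append(np.exp(num - den))
        mean = np.mean(ratios)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert mean == pytest.approx(1.0, abs=4 * se + 0.01)


class TestExactLikelihood:
    def test_single_asv_matches_two_state_pruning(self, four_tip_tree):
        D = np.array([[0.0]])
        p = RepertoireParams(0.5, 0.3, 0.0)
        tips = np.array([[1.0], [0.0], [1.0], [1.0]])
        joint = exact_tip_likelihood(four_tip_tree, tips, p, D, 0.4)
        prune = independent_pruning_loglik(four_tip_tree, tips, p, 0.4)
        assert joint == pytest.approx(prune, abs=1e-10)

    def test_beta_zero_factorizes(self, four_tip_tree):
        rng = np.random.default_rng(1)
        for rep in range(5):
            m = int(rng.integers(2, 6))
            pts = rng.random((m, 2))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            p = RepertoireParams(*rng.uniform(0.1, 0.9, size=2), 0.0)
            tips = (rng.random((4, m)) < 0.5).astype(float)
            joint = exact_tip_likelihood(four_tip_tree, tips, p, D, 0.5)
            prune = independent_pruning_loglik(four_tip_tree, tips, p, 0.5)
            assert abs(joint - prune) < 1e-10 * max(1, abs(joint))

    def test_likelihood_sums_to_one_over_all_tip_matrices(self):
        tree = parse_newick("(A:1.0,B:1.0);")
        D = np.array([[0.0, 0.6], [0.6, 0.0]])
        p = RepertoireParams(0.7, 0.4, 1.3)
        total = 0.0
        for pattern in range(16):
            tips = np.array([[(pattern >> 0) & 1, (pattern >> 1) & 1],
                             [(pattern >> 2) & 1, (pattern >> 3) & 1]],
                            dtype=float)
            total += np.exp(exact_tip_likelihood(tree, tips, p, D, 0.3))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_pattern_distribution_sums_to_one(self, three_tip_tree,
                                              asv_distances_3):
        p = RepertoireParams(0.5, 0.4, 2.0)
        _, probs = joint_tip_pattern_distribution(three_tip_tree, p,
                                                  asv_distances_3, 0.5)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (probs >= 0).all()

    def test_refuses_large_state_space(self, three_tip_tree):
        D = np.zeros((15, 15))
        p = RepertoireParams(0.5, 0.4, 0.0)
        with pytest.raises(ValueError, match="14"):
            exact_tip_likelihood(three_tip_tree, np.zeros((3, 15)), p, D, 0.5)

    def test_pruning_requires_beta_zero(self, four_tip_tree):
        with pytest.raises(ValueError, match="beta"):
            independent_pruning_loglik(four_tip_tree, np.zeros((4, 1)),
                                       RepertoireParams(0.5, 0.5, 1.0), 0.5)

    def test_stationary_limit_on_long_branch(self):
        """lambda_gain = lambda_loss on a very long branch: either tip state
        is equally likely regardless of the root."""
        tree = parse_newick("(A:500,B:500);")
        D = np.array([[0.0]])
        p = RepertoireParams(0.3, 0.3, 0.0)
        for state in (0.0, 1.0):
            ll = independent_pruning_loglik(tree, np.array([[state], [1.0]]),
                                            p, 0.9)
            assert np.exp(ll) == pytest.approx(0.25, abs=1e-6)
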