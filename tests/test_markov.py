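import math

import numpy as np
import pytest

from ethosyntax.markov import (
    ModelError,
    ModelScore,
    StateSpaceError,
    TransitionCounts,
    TransitionMatrix,
    bic_score,
    build_state_space,
    compare_matrices,
    count_free_parameters,
    count_transitions,
    half_bout_boundary,
    log_likelihood,
    mle_transition_matrix,
    rank_models,
    split_phases,
)
from conftest import make_bouts, make_toy_fly


def seq(actions, cats=None):
    durs = np.ones(len(actions))
    return make_bouts(actions, durs, cats)


class TestStateSpace:
    def test_eighteen_states(self):
        assert build_state_space(("f", "h", "a", "b", "w", "wk"), 3).v == 18

    def test_six_states(self):
        assert build_state_space(("f", "h", "a", "b", "w", "wk"), 1).v == 6

    def test_twelve_states(self):
        assert build_state_space(("f", "h", "a", "b", "w", "wk"), 2).v == 12

    def test_ordering(self):
        space = build_state_space(("x", "y"), 2)
        assert space.states == (("x", 0), ("x", 1), ("y", 0), ("y", 1))
        assert space.v == 4

    def test_duplicate_action_rejected(self):
        with pytest.raises(StateSpaceError):
            build_state_space(("h", "h"), 1)

    def test_labels_use_duration_letters(self):
        space = build_state_space(("h", "f"), 3)
        assert space.labels()[:3] == ["h.s", "h.m", "h.l"]


class TestCountTransitions:
    def test_hand_count_one_fly(self):
        space = build_state_space(("f", "h", "wk"), 1)
        counts = count_transitions([seq(["h", "f", "h", "f", "wk"])], space)
        h, f, wk = space.index("h"), space.index("f"), space.index("wk")
        assert counts.counts[h, f] == 2
        assert counts.counts[f, h] == 1
        assert counts.counts[f, wk] == 1
        assert counts.n_total == 4

    def test_no_cross_fly_pooling(self):
        space = build_state_space(("f", "h"), 1)
        counts = count_transitions([seq(["h", "f"]), seq(["f", "h"])], space)
        h, f = space.index("h"), space.index("f")
        assert counts.counts[h, f] == 1
        assert counts.counts[f, h] == 1
        assert counts.n_total == 2

    def test_unbinned_rejected_when_n_bins_gt_1(self):
        space = build_state_space(("f", "h"), 2)
        with pytest.raises(ModelError):
            count_transitions([seq(["h", "f"])], space)

    def test_counts_converge_to_stationary_flow(self):
        # independent oracle: brute-force tally of simulated pairs
        rng = np.random.default_rng(5)
        space = build_state_space(("f", "h", "a"), 1)
        M = np.array([[0.0, 0.7, 0.3], [0.4, 0.0, 0.6], [0.5, 0.5, 0.0]])
        flies = []
        tally = np.zeros((3, 3))
        for _ in range(100):
            states = [int(rng.integers(3))]
            for _ in range(99):
                states.append(int(rng.choice(3, p=M[states[-1]])))
            for a, b in zip(states[:-1], states[1:]):
                tally[a, b] += 1
            flies.append(
                make_bouts([space.actions[s] for s in states], np.ones(100))
            )
        counts = count_transitions(flies, space)
        assert np.array_equal(counts.counts, tally.astype(int))


class TestMLE:
    def test_hand_normalization(self):
        space = build_state_space(("f", "h", "wk"), 1)
        m = mle_transition_matrix(count_transitions([seq(["h", "f", "h", "f", "wk"])], space))
        f, h, wk = space.index("f"), space.index("h"), space.index("wk")
        assert m.probs[f, h] == pytest.approx(0.5)
        assert m.probs[f, wk] == pytest.approx(0.5)
        assert m.probs[h, f] == pytest.approx(1.0)

    def test_zero_row_is_unsupported_not_nan(self):
        space = build_state_space(("f", "h", "wk"), 1)
        m = mle_transition_matrix(count_transitions([seq(["h", "f"])], space))
        wk = space.index("wk")
        assert not m.row_support[wk]
        assert not np.isnan(m.probs).any()
        assert m.probs[wk].sum() == 0.0

    def test_parameter_recovery_18_states(self):
        # fixed-seed recovery: >= 50k transitions from a known 18-state matrix
        rng = np.random.default_rng(11)
        space = build_state_space(("f", "h", "a", "b", "w", "wk"), 3)
        v, nb = space.v, space.n_bins
        gen = rng.uniform(0.2, 1.0, (v, v))
        gen[space.same_action_mask()] = 0.0
        gen /= gen.sum(axis=1, keepdims=True)
        cum = np.cumsum(gen, axis=1)
        n_steps = 200_000
        states = np.empty(n_steps + 1, dtype=np.int64)
        states[0] = 0
        u = rng.random(n_steps)
        for t in range(n_steps):
            states[t + 1] = np.searchsorted(cum[states[t]], u[t])
        etho = make_bouts(
            np.asarray(space.actions)[states // nb], np.ones(n_steps + 1), states % nb
        )
        m = mle_transition_matrix(count_transitions([etho], space))
        assert counts_max_error(m.probs, gen) <= 0.02


def counts_max_error(a, b):
    return float(np.abs(a - b).max())


class TestLikelihoodAndBIC:
    def test_deterministic_chain_loglik_zero(self):
        space = build_state_space(("f", "h"), 1)
        m = mle_transition_matrix(count_transitions([seq(["h", "f", "h"])], space))
        assert log_likelihood([seq(["h", "f", "h"])], m) == pytest.approx(0.0)

    def test_log_half(self):
        space = build_state_space(("f", "h", "wk"), 1)
        cohort = [seq(["h", "f", "h"]), seq(["h", "f", "wk"])]
        m = mle_transition_matrix(count_transitions(cohort, space))
        assert log_likelihood([seq(["h", "f"])], m) == pytest.approx(math.log(1.0))
        assert log_likelihood([seq(["f", "h"])], m) == pytest.approx(math.log(0.5))

    def test_cohort_likelihood_is_sum_of_per_fly(self):
        cohort = [make_toy_fly(s) for s in (1, 2, 3)]
        space = build_state_space(("f", "h", "a", "wk"), 3)
        m = mle_transition_matrix(count_transitions(cohort, space))
        total = log_likelihood(cohort, m)
        assert total == pytest.approx(sum(log_likelihood([e], m) for e in cohort))

    def test_zero_probability_transition_reported(self):
        space = build_state_space(("f", "h", "wk"), 1)
        m = mle_transition_matrix(count_transitions([seq(["h", "f", "h"])], space))
        ll, offending = log_likelihood([seq(["h", "wk"])], m, return_offending=True)
        assert ll == -math.inf
        assert offending == [(0, 0, space.index("h"), space.index("wk"))]

    def test_structural_k_18_states(self):
        space = build_state_space(("f", "h", "a", "b", "w", "wk"), 3)
        probs = np.full((18, 18), 1 / 15.0)
        probs[space.same_action_mask()] = 0.0
        m = TransitionMatrix(probs, space, np.ones(18, dtype=bool))
        assert count_free_parameters(m, "structural") == 252

    def test_structural_k_6_states(self):
        space = build_state_space(("f", "h", "a", "b", "w", "wk"), 1)
        probs = np.full((6, 6), 0.2)
        np.fill_diagonal(probs, 0.0)
        m = TransitionMatrix(probs, space, np.ones(6, dtype=bool))
        assert count_free_parameters(m, "structural") == 24

    def test_unsupported_row_reduces_k(self):
        space = build_state_space(("f", "h", "wk"), 1)
        m = mle_transition_matrix(count_transitions([seq(["h", "f"])], space))
        full = TransitionMatrix(
            np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]], dtype=float),
            space,
            np.ones(3, dtype=bool),
        )
        # two of three rows are unsupported (only h has an outgoing transition)
        assert (
            count_free_parameters(full, "structural")
            - count_free_parameters(m, "structural")
            == 2 * (space.v - space.n_bins - 1)
        )

    def test_bic_arithmetic(self):
        score = ModelScore(
            log_likelihood=-200.0,
            k=10,
            n=100,
            bic=math.log(100) * 10 + 400.0,
            convention="structural",
        )
        assert score.bic == pytest.approx(446.0517018598809)

    def test_bic_identity_enforced(self):
        with pytest.raises(ModelError):
            ModelScore(log_likelihood=-200.0, k=10, n=100, bic=0.0, convention="structural")

    def test_identical_models_identical_bic(self, toy_cohort, toy_space):
        m = mle_transition_matrix(count_transitions(toy_cohort, toy_space))
        s1 = bic_score(toy_cohort, m)
        s2 = bic_score(toy_cohort, m)
        assert s1.bic == s2.bic

    def test_rank_models_orders_by_bic(self):
        a = ModelScore(-10.0, 1, 10, math.log(10) * 1 + 20.0, "structural")
        b = ModelScore(-5.0, 1, 10, math.log(10) * 1 + 10.0, "structural")
        assert rank_models({"a": a, "b": b}) == ["b", "a"]

    def test_mle_maximizes_likelihood_among_candidates(self, toy_cohort, toy_space):
        m = mle_transition_matrix(count_transitions(toy_cohort, toy_space))
        ll_mle = log_likelihood(toy_cohort, m)
        rng = np.random.default_rng(0)
        for _ in range(5):
            probs = rng.uniform(0.05, 1.0, m.probs.shape)
            probs[toy_space.same_action_mask()] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            other = TransitionMatrix(probs, toy_space, np.ones(toy_space.v, dtype=bool))
            assert log_likelihood(toy_cohort, other) <= ll_mle + 1e-9


class TestSplitPhases:
    def test_half_bout_boundary(self):
        etho = make_bouts(["h", "f"] * 5, np.ones(10))
        assert half_bout_boundary([etho]) == pytest.approx(5.0 / 60.0)

    def test_edge_bouts_indexing(self):
        actions = ["h" if i % 2 == 0 else "f" for i in range(1000)]
        etho = make_bouts(actions, np.ones(1000))
        part = split_phases([etho], rule="edge-bouts", n_edge_bouts=200)
        assert part.early[0].n_bouts == 200
        assert part.late[0].n_bouts == 200
        assert part.early[0].actions.tolist() == actions[:200]
        assert part.late[0].actions.tolist() == actions[800:]

    def test_fixed_time_split_conserves_time(self):
        etho = make_bouts(["h", "f", "h", "f"], [30.0, 30.0, 30.0, 30.0])
        part = split_phases([etho], rule="fixed-time", boundary_min=1.0)
        assert part.early[0].total_time + part.late[0].total_time == pytest.approx(
            etho.total_time
        )

    def test_straddling_bout_assigned_by_start(self):
        etho = make_bouts(["h", "f"], [50.0, 50.0])
        part = split_phases([etho], rule="fixed-time", boundary_min=1.0)
        # second bout starts at 50 s < 60 s boundary -> early
        assert part.early[0].n_bouts == 2
        assert not part.late

    def test_short_fly_warns(self):
        etho = make_bouts(["h", "f"] * 5, np.ones(10))
        with pytest.warns(UserWarning):
            split_phases([etho], rule="edge-bouts", n_edge_bouts=200)

    def test_thirds_discards_middle(self):
        actions = ["h" if i % 2 == 0 else "f" for i in range(9)]
        etho = make_bouts(actions, np.ones(9))
        part = split_phases([etho], rule="thirds")
        assert part.early[0].n_bouts == 3
        assert part.late[0].n_bouts == 3
        assert part.early[0].actions.tolist() == actions[:3]
        assert part.late[0].actions.tolist() == actions[6:]

    def test_half_bouts_recovery_on_synthetic_drift(self):
        from ethosyntax.synth import GroundTruthSpec, generate_cohort

        spec = GroundTruthSpec(n_flies=8, total_time_min=27.8, seed=21)
        cohort = generate_cohort(spec)
        part = split_phases(list(cohort.bout_ethograms), rule="half-bouts")
        # the generator drifts linearly to t_switch=13; the half-bout time
        # should land within a couple of minutes of the progression midpoint
        assert abs(part.boundary_min - 13.0) < 4.0


class TestCompareMatrices:
    def _pair(self, shift=0.0):
        space = build_state_space(("x", "y"), 2)
        probs = np.array(
            [
                [0.0, 0.0, 0.6, 0.4],
                [0.0, 0.0, 0.5, 0.5],
                [0.7, 0.3, 0.0, 0.0],
                [0.2, 0.8, 0.0, 0.0],
            ]
        )
        shifted = probs.copy()
        shifted[0, 2] += shift
        shifted[0, 3] -= shift
        support = np.ones(4, dtype=bool)
        return (
            TransitionMatrix(probs, space, support),
            TransitionMatrix(shifted, space, support),
        )

    def test_identity_passes_every_threshold(self):
        m1, m2 = self._pair(0.0)
        cmp = compare_matrices(m1, m1, thresholds=[0.05, 0.01, 1e-9])
        for cnt, frac in cmp.below_threshold.values():
            assert frac == 1.0

    def test_shifted_entry_thresholds(self):
        m1, m2 = self._pair(0.06)
        cmp = compare_matrices(m1, m2, thresholds=[0.05, 0.10])
        n = cmp.n_joint_nonzero
        assert cmp.below_threshold[0.05][0] == n - 2  # both shifted entries fail
        assert cmp.below_threshold[0.10][0] == n

    def test_mismatched_spaces_rejected(self):
        m1, _ = self._pair()
        space = build_state_space(("x", "y"), 1)
        other = TransitionMatrix(
            np.array([[0.0, 1.0], [1.0, 0.0]]), space, np.ones(2, dtype=bool)
        )
        with pytest.raises(ModelError):
            compare_matrices(m1, other)

    def test_two_halves_of_stationary_cohort_converge(self):
        from ethosyntax.synth import GroundTruthSpec, generate_cohort

        spec = GroundTruthSpec(
            n_flies=12, total_time_min=27.8, drift=None, seed=3, duration_coupling=0.4
        )
        fracs = {}
        for n_flies in (4, 32):
            spec = GroundTruthSpec(
                n_flies=n_flies,
                total_time_min=27.8,
                drift=None,
                seed=3,
                duration_coupling=0.4,
            )
            truth = generate_cohort(spec)
            space = truth.model.state_space
            part = split_phases(
                list(truth.bout_ethograms), rule="fixed-time", boundary_min=13.9
            )
            m_early = mle_transition_matrix(count_transitions(list(part.early), space))
            m_late = mle_transition_matrix(count_transitions(list(part.late), space))
            cmp = compare_matrices(m_early, m_late, thresholds=[0.05])
            fracs[n_flies] = cmp.below_threshold[0.05][1]
        assert fracs[32] > fracs[4]
        assert fracs[32] > 0.95
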