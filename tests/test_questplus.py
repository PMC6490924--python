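"""Adaptive trial placement: grid validity, information gain, Bayes updates."""

import numpy as np
import pytest

import colormat as cm
from colormat.questplus_engine import (
    LikelihoodMatrix,
    QuestParameterGrid,
    QuestState,
    candidate_pairs,
    expected_entropies,
    posterior_mode,
    stimuli_in_range,
)


class TestGrid:
    def test_raw_size_matches_design(self):
        assert QuestParameterGrid().raw_size == 32000

    def test_default_level_ranges(self):
        g = QuestParameterGrid()
        assert g.linear_levels[0] == 0.5 and g.linear_levels[-1] == 6.0
        assert len(g.linear_levels) == 5
        assert g.quadratic_levels[0] == -0.3 and g.quadratic_levels[-1] == 0.3
        assert len(g.quadratic_levels) == 4 and len(g.cubic_levels) == 4
        assert g.weight_levels[0] == 0.05 and g.weight_levels[-1] == 0.95
        assert len(g.weight_levels) == 5

    def test_valid_combos_satisfy_constraints(self):
        _, pos = QuestParameterGrid().valid_dimension_combos()
        assert len(pos) > 0
        assert np.all(np.diff(pos, axis=1) >= 0.25)
        assert np.all(np.abs(pos) <= 20.0)

    def test_candidate_pair_counts(self):
        assert len(candidate_pairs(3)) == 1176
        assert len(candidate_pairs(2)) == 300
        assert len(candidate_pairs(1)) == 36
        assert len(stimuli_in_range(3)) == 49

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            candidate_pairs(4)


@pytest.fixture(scope="module")
def small_state(small_grid, euclid_table):
    return cm.init_quest(small_grid, 1, euclid_table)


class TestInit:
    def test_uniform_prior_and_entropy(self, small_state):
        n = len(small_state.posterior)
        np.testing.assert_allclose(small_state.posterior, 1.0 / n)
        assert small_state.entropy == pytest.approx(np.log(n))

    def test_likelihoods_in_unit_interval(self, small_state):
        assert np.all(small_state.matrix.L > 0)
        assert np.all(small_state.matrix.L < 1)

    def test_restricted_range_pair_count(self, small_state):
        assert len(small_state.matrix.pairs) == 36

    def test_empty_grid_rejected(self, euclid_table):
        bad = QuestParameterGrid(linear_levels=(0.01,),
                                 quadratic_levels=(0.0,),
                                 cubic_levels=(0.0,),
                                 weight_levels=(0.5,))
        with pytest.raises(ValueError, match="empty"):
            cm.init_quest(bad, 1, euclid_table)


def _toy_state(L, posterior=None):
    pairs = [(cm.NominalStimulus(0, 1), cm.NominalStimulus(1, 0)),
             (cm.NominalStimulus(0, 2), cm.NominalStimulus(2, 0))][:L.shape[1]]
    n = L.shape[0]
    post = np.full(n, 1.0 / n) if posterior is None else posterior
    return QuestState(QuestParameterGrid(), 3, post,
                      LikelihoodMatrix(pairs, L))


class TestNextStimulus:
    def test_hand_computed_two_combo_example(self):
        # pair A separates the combos (0.9 vs 0.1), pair B barely (0.6 vs 0.4)
        L = np.array([[0.9, 0.6], [0.1, 0.4]])
        state = _toy_state(L)
        eh = expected_entropies(state)
        assert eh[0] < eh[1]
        assert cm.next_stimulus(state) == state.matrix.pairs[0]

    def test_uninformative_pair_never_preferred(self):
        # a pair with likelihood 0.5 for every combo gains nothing
        L = np.array([[0.5, 0.8], [0.5, 0.2]])
        state = _toy_state(L)
        eh = expected_entropies(state)
        assert eh[1] < eh[0] - 1e-6
        # zero expected gain: entropy unchanged for the flat pair
        assert eh[0] == pytest.approx(state.entropy, abs=1e-9)

    def test_concentrated_posterior_ties_break_to_lowest_index(self):
        L = np.array([[0.7, 0.6], [0.3, 0.4]])
        state = _toy_state(L, posterior=np.array([1.0, 0.0]))
        eh = expected_entropies(state)
        np.testing.assert_allclose(eh, 0.0, atol=1e-9)
        assert cm.next_stimulus(state) == state.matrix.pairs[0]


class TestUpdate:
    def test_one_step_bayes_arithmetic(self):
        L = np.array([[0.9, 0.6], [0.1, 0.4]])
        state = _toy_state(L)
        new = cm.update_posterior(state, state.matrix.pairs[0], 1)
        np.testing.assert_allclose(new.posterior, [0.9, 0.1])
        # original state untouched
        np.testing.assert_allclose(state.posterior, [0.5, 0.5])

    def test_uninformative_pair_leaves_posterior_unchanged(self):
        L = np.array([[0.5, 0.8], [0.5, 0.2]])
        state = _toy_state(L)
        new = cm.update_posterior(state, state.matrix.pairs[0], 2)
        np.testing.assert_allclose(new.posterior, state.posterior)

    def test_updates_commute(self, small_state):
        pairs = small_state.matrix.pairs
        a = cm.update_posterior(
            cm.update_posterior(small_state, pairs[0], 1), pairs[5], 2)
        b = cm.update_posterior(
            cm.update_posterior(small_state, pairs[5], 2), pairs[0], 1)
        np.testing.assert_allclose(a.posterior, b.posterior, atol=1e-12)

    def test_swapped_pair_orientation_flips_choice(self, small_state):
        p = small_state.matrix.pairs[3]
        direct = cm.update_posterior(small_state, p, 1)
        flipped = cm.update_posterior(small_state, (p[1], p[0]), 2)
        np.testing.assert_allclose(direct.posterior, flipped.posterior)

    def test_unknown_pair_rejected(self, small_state):
        alien = (cm.NominalStimulus(-3, -3), cm.NominalStimulus(3, 3))
        with pytest.raises(ValueError, match="candidate set"):
            cm.update_posterior(small_state, alien, 1)


class TestAdaptiveSessions:
    def test_entropy_decreases_over_simulated_trials(self, small_grid,
                                                     euclid_table):
        rng = np.random.default_rng(0)
        observer = cm.GeneratingObserver(0.5, cm.linear_mapping(1.5))
        state = cm.init_quest(small_grid, 1, euclid_table)
        h0 = state.entropy
        from colormat.session_simulator import _respond
        for _ in range(60):
            pair = cm.next_stimulus(state)
            state = cm.update_posterior(state, pair, _respond(observer, pair,
                                                              rng))
        assert state.entropy < h0 - 1.0

    def test_posterior_concentrates_on_generating_combo(self, small_grid,
                                                        euclid_table):
        # generating observer sits exactly on a grid point
        hits = 0
        from colormat.session_simulator import _respond
        for seed in range(5):
            rng = np.random.default_rng(seed)
            observer = cm.GeneratingObserver(
                0.8, cm.PositionalMapping("cubic", (1.5, 0.2, 0.0),
                                          (3.0, -0.2, 0.0)))
            state = cm.init_quest(small_grid, 2, euclid_table)
            for _ in range(150):
                pair = cm.next_stimulus(state)
                state = cm.update_posterior(
                    state, pair, _respond(observer, pair, rng))
            w, ct, mt = posterior_mode(state)
            if (w == 0.8 and tuple(ct) == (1.5, 0.2, 0.0)
                    and tuple(mt) == (3.0, -0.2, 0.0)):
                hits += 1
        assert hits >= 3
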