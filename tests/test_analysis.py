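"""Bootstrap intervals, trade-off curves, slope ratio and recovery."""

import numpy as np
import pytest

import colormat as cm
from colormat.analysis import dimension_slope


@pytest.fixture(scope="module")
def fitted_solution(short_session, euclid_table):
    return cm.fit_model(short_session, cm.ModelSpec("linear", "euclidean"),
                        euclid_table, cm.FitConfig(n_starts=4, seed=0))


class TestSlopeRatio:
    def test_identity_positions_ratio_one(self):
        sol = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                               cm.linear_mapping(1.0))
        assert cm.slope_ratio(sol) == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        sol = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                               cm.linear_mapping(1.0, 2.0))
        assert cm.slope_ratio(sol) == pytest.approx(0.5)

    def test_full_variant_matches_regression_oracle(self):
        params_c = (-7.0, -4.0, -1.5, 2.0, 4.5, 8.0)
        params_m = (-5.0, -3.0, -1.0, 1.0, 3.0, 5.0)
        sol = cm.ModelSolution(
            cm.ModelSpec("full", "euclidean"), 0.4,
            cm.PositionalMapping("full", params_c, params_m))
        levels = np.arange(-3, 4)
        slope = np.polyfit(levels, sol.mapping.positions("color"), 1)[0]
        slope_m = np.polyfit(levels, sol.mapping.positions("material"), 1)[0]
        assert cm.slope_ratio(sol) == pytest.approx(slope / slope_m)
        assert dimension_slope(sol.mapping.positions("color")) == \
            pytest.approx(slope)


class TestTradeoffCurves:
    def test_target_vs_target_at_chance(self, fitted_solution, euclid_table):
        curves = cm.tradeoff_functions(fitted_solution, euclid_table)
        assert curves.curve(0)[3] == pytest.approx(0.5, abs=0.02)

    def test_m0_curve_approaches_one_at_large_color_offset(self,
                                                           euclid_table):
        # steep mapping: the material match at |C|=3 sits far out, so the
        # color match (identical to the target) is chosen almost always
        sol = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                               cm.linear_mapping(3.0))
        m0 = cm.tradeoff_functions(sol, euclid_table).curve(0)
        assert m0[0] > 0.95 and m0[-1] > 0.95

    def test_curves_monotone_in_color_offset_magnitude(self, fitted_solution,
                                                       euclid_table):
        curves = cm.tradeoff_functions(fitted_solution, euclid_table)
        for m in range(-3, 4):
            c = curves.curve(m)
            assert np.all(np.diff(c[3:]) >= -0.03)      # rightward
            assert np.all(np.diff(c[:4][::-1]) >= -0.03)  # leftward

    def test_symmetric_solution_gives_coincident_plus_minus_curves(
            self, euclid_table):
        sol = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                               cm.linear_mapping(1.2, 0.8))
        curves = cm.tradeoff_functions(sol, euclid_table)
        # the Monte-Carlo table is only statistically mirror-symmetric, so
        # equated steps coincide up to table noise
        np.testing.assert_allclose(curves.curve(-1), curves.curve(1),
                                   atol=0.03)

    def test_curves_depend_only_on_weighted_geometry(self, euclid_table):
        a = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                             cm.linear_mapping(2.0, 1.0))
        b = cm.ModelSolution(cm.ModelSpec("full", "euclidean"), 0.5,
                             cm.PositionalMapping(
                                 "full",
                                 (-6.0, -4.0, -2.0, 2.0, 4.0, 6.0),
                                 (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)))
        ca = cm.tradeoff_functions(a, euclid_table)
        cb = cm.tradeoff_functions(b, euclid_table)
        np.testing.assert_allclose(ca.probabilities, cb.probabilities,
                                   atol=1e-9)


class TestBootstrap:
    def test_seeded_determinism_and_ci_order(self, short_session,
                                             fitted_solution, euclid_table):
        a = cm.bootstrap_weights(short_session, fitted_solution, euclid_table,
                                 n_iterations=8, seed=4)
        b = cm.bootstrap_weights(short_session, fitted_solution, euclid_table,
                                 n_iterations=8, seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert 0.0 <= a.ci_low <= a.ci_high <= 1.0
        assert a.n_failures == 0

    def test_interval_brackets_generating_weight(self, short_session,
                                                 fitted_solution,
                                                 euclid_table):
        res = cm.bootstrap_weights(short_session, fitted_solution,
                                   euclid_table, n_iterations=12, seed=5)
        # generous check: the 68% interval of a well-posed simulated dataset
        # should sit in the neighborhood of the generating weight 0.5
        assert res.ci_low - 0.2 < 0.5 < res.ci_high + 0.2

    def test_weight_slope_ratio_tradeoff_is_negative(self, short_session,
                                                     fitted_solution,
                                                     euclid_table):
        res = cm.bootstrap_weights(short_session, fitted_solution,
                                   euclid_table, n_iterations=20, seed=6)
        ratios = np.array([cm.slope_ratio(s) for s in res.solutions])
        r = np.corrcoef(res.weights, ratios)[0, 1]
        assert r < 0

    def test_degenerate_data_all_non_identifiable(self, euclid_table,
                                                  fitted_solution):
        trials = [cm.TrialRecord(cm.NominalStimulus(1, 1),
                                 cm.NominalStimulus(1, 1), 1)
                  for _ in range(50)]
        sol = cm.ModelSolution(cm.ModelSpec("linear", "euclidean"), 0.5,
                               cm.linear_mapping(1.0))
        res = cm.bootstrap_weights(trials, sol, euclid_table,
                                   n_iterations=5, seed=0)
        assert res.n_non_identifiable == 5


class TestRecovery:
    def test_small_scale_recovery_preserves_rank_order(self, small_grid,
                                                       tables):
        observers = [cm.GeneratingObserver(w, cm.linear_mapping(1.0))
                     for w in (0.2, 0.8)]
        design = cm.SessionDesign(n_blocks=2)
        reports = cm.recovery_study(
            observers, design, small_grid, tables, seed=7,
            fit_config=cm.FitConfig(n_starts=4),
        )
        assert [r.n_trials for r in reports] == [540, 540]
        ws = [r.recovered_w for r in reports]
        assert ws[0] < ws[1]
        for r in reports:
            r.solution.mapping.validate()
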