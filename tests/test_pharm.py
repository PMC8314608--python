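"""Dose-response fitting, IC50, median-effect / CI and ZIP scoring:
model-true exact recovery, algebraic oracles, and the interpretation
thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import targetfunnel as tf
from targetfunnel import scenarios
from targetfunnel.pharm import (absolute_ic50, classify_ci, combination_index,
                                fit_four_pl, fit_median_effect, fold_resistance,
                                four_pl, zip_delta)

DOSES = np.logspace(-2, 1, 8)


class TestFourPL:
    def test_exact_recovery_noise_free(self):
        y = four_pl(DOSES, 0.0, 1.0, 0.5, 1.2)
        fit = fit_four_pl(DOSES, y)
        assert fit.converged
        for got, want in [(fit.bottom, 0.0), (fit.top, 1.0),
                          (fit.ec50, 0.5), (fit.hill, 1.2)]:
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_midpoint_identity(self):
        fit = fit_four_pl(DOSES, four_pl(DOSES, 0.0, 1.0, 0.5, 2.0))
        assert four_pl(0.5, fit.bottom, fit.top, fit.ec50, fit.hill) == pytest.approx(0.5, abs=1e-9)

    def test_flat_data_flagged_not_converged(self):
        fit = fit_four_pl(DOSES, np.full(8, 0.7))
        assert not fit.converged
        assert fit.bottom == pytest.approx(fit.top)

    def test_noisy_plate_median_ec50_within_10pct(self):
        # simulation oracle against generator truth; 60 plates is enough to
        # pin the median well inside the band
        estimates = []
        for seed in range(60):
            spec = tf.PlateSpec(0.0, 1.0, 0.5, 1.2, tuple(DOSES), 3, 0.05, seed)
            plate = tf.generate_dose_response_plate(spec)
            fit = fit_four_pl(plate["dose"].to_numpy(), plate["response"].to_numpy())
            if fit.converged:
                estimates.append(fit.ec50)
        assert abs(np.median(estimates) - 0.5) / 0.5 < 0.10

    def test_requires_four_distinct_doses(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_four_pl([0.1, 0.1, 1.0, 1.0], [1, 1, 0, 0])

    def test_refit_idempotent(self):
        fit = fit_four_pl(DOSES, four_pl(DOSES, 0.1, 0.9, 0.3, 1.5))
        refit = fit_four_pl(DOSES, four_pl(DOSES, fit.bottom, fit.top, fit.ec50, fit.hill))
        assert absolute_ic50(refit) == pytest.approx(absolute_ic50(fit), rel=1e-6)


class TestIC50:
    def _fit(self, bottom, top, ec50=1.0, hill=1.3):
        return tf.FourPLFit(bottom, top, ec50, hill, 0.0, True)

    def test_equals_ec50_for_full_range_curve(self):
        assert absolute_ic50(self._fit(0.0, 1.0)) == pytest.approx(1.0)

    def test_crossing_matches_bisection(self):
        fit = self._fit(0.4, 1.0, ec50=2.0, hill=1.7)
        ic50 = absolute_ic50(fit)
        ref = optimize.brentq(
            lambda x: four_pl(x, fit.bottom, fit.top, fit.ec50, fit.hill) - 0.5,
            1e-9, 1e9)
        assert ic50 == pytest.approx(ref, rel=1e-9)

    def test_floor_above_half_not_reached(self):
        assert absolute_ic50(self._fit(0.6, 1.0)) is None

    def test_non_converged_rejected(self):
        with pytest.raises(ValueError):
            absolute_ic50(tf.FourPLFit(0, 1, 1, 1, 0.0, False))


class TestFoldResistance:
    def test_simple_ratio(self):
        assert fold_resistance(2.0, 1.0) == pytest.approx(2.0)
        assert fold_resistance(1.5, 1.5) == pytest.approx(1.0)

    def test_not_reached_propagates(self):
        assert fold_resistance(None, 1.0) is None
        assert fold_resistance(1.0, None) is None

    def test_planted_2000x_shift_recovered(self):
        pair = scenarios.resistance_pair(seed=5)
        ic50s = {}
        for name, spec in pair.items():
            plate = tf.generate_dose_response_plate(spec)
            fit = fit_four_pl(plate["dose"].to_numpy(), plate["response"].to_numpy())
            ic50s[name] = absolute_ic50(fit)
        ratio = fold_resistance(ic50s["resistant"], ic50s["parental"])
        assert ratio == pytest.approx(2000.0, rel=0.25)


class TestMedianEffect:
    def test_model_true_exact_recovery(self):
        d = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fa = 1.0 / (1.0 + (1.0 / d) ** 1.0)    # Dm=1, m=1
        fit = fit_median_effect(d, fa)
        assert fit.dm == pytest.approx(1.0, rel=1e-9)
        assert fit.m == pytest.approx(1.0, rel=1e-9)
        assert fit.r_fit == pytest.approx(1.0)

    def test_fa_half_at_dm(self):
        fit = fit_median_effect([0.5, 2.0], [1 / (1 + (1.5 / 0.5)), 1 / (1 + 1.5 / 2.0)])
        fa_at_dm = 1.0 / (1.0 + (fit.dm / fit.dm) ** fit.m)
        assert fa_at_dm == pytest.approx(0.5)

    def test_two_point_algebra_oracle(self):
        # slope/intercept from direct two-point algebra on noise-free pairs
        d = np.array([0.3, 3.0])
        fa = 1.0 / (1.0 + (2.0 / d) ** 1.7)    # Dm=2, m=1.7
        fit = fit_median_effect(d, fa)
        y = np.log(fa / (1 - fa)); x = np.log(d)
        m = (y[1] - y[0]) / (x[1] - x[0])
        dm = np.exp(x[0] - y[0] / m)
        assert fit.m == pytest.approx(m, rel=1e-12)
        assert fit.dm == pytest.approx(dm, rel=1e-9)

    def test_extreme_fa_excluded(self):
        fit = fit_median_effect([0.1, 1.0, 10.0, 100.0], [0.0, 0.4, 0.6, 1.0])
        assert fit.n_used == 2 and fit.n_excluded == 2

    def test_too_few_usable_points_rejected(self):
        with pytest.raises(ValueError):
            fit_median_effect([1.0, 2.0], [0.0, 1.0])


class TestCombinationIndex:
    def test_hand_value(self):
        fa_ = tf.MedianEffectFit(1.0, 1.0, 1.0, 5, 0)
        fb = tf.MedianEffectFit(2.0, 1.0, 1.0, 5, 0)
        assert combination_index(0.5, 0.5, 0.5, fa_, fb) == pytest.approx(0.75)

    @given(dm=st.floats(0.05, 20), m=st.floats(0.3, 4), fa=st.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_sham_combination_ci_is_one(self, dm, m, fa):
        # drug combined with itself, each arm at half dose -> additivity
        fit = tf.MedianEffectFit(dm, m, 1.0, 5, 0)
        d = dm * (fa / (1 - fa)) ** (1 / m)
        assert combination_index(d / 2, d / 2, fa, fit, fit) == pytest.approx(1.0, abs=1e-9)

    def test_doubling_doses_doubles_ci(self):
        fa_ = tf.MedianEffectFit(1.0, 1.3, 1.0, 5, 0)
        fb = tf.MedianEffectFit(3.0, 0.8, 1.0, 5, 0)
        ci1 = combination_index(0.4, 0.7, 0.6, fa_, fb)
        ci2 = combination_index(0.8, 1.4, 0.6, fa_, fb)
        assert ci2 == pytest.approx(2 * ci1)

    def test_unit_rescaling_invariance(self):
        fa_ = tf.MedianEffectFit(1.0, 1.3, 1.0, 5, 0)
        fb = tf.MedianEffectFit(3.0, 0.8, 1.0, 5, 0)
        scale = 1000.0  # uM -> nM
        fa_s = tf.MedianEffectFit(fa_.dm * scale, fa_.m, 1.0, 5, 0)
        fb_s = tf.MedianEffectFit(fb.dm * scale, fb.m, 1.0, 5, 0)
        assert combination_index(0.4 * scale, 0.7 * scale, 0.6, fa_s, fb_s) == \
            pytest.approx(combination_index(0.4, 0.7, 0.6, fa_, fb), rel=1e-12)

    def test_fa_boundary_rejected(self):
        fit = tf.MedianEffectFit(1.0, 1.0, 1.0, 5, 0)
        for fa in (0.0, 1.0):
            with pytest.raises(ValueError):
                combination_index(1, 1, fa, fit, fit)

    def test_classes(self):
        assert classify_ci(0.5) == "synergistic"
        assert classify_ci(1.0) == "additive"
        assert classify_ci(1.5) == "antagonistic"


class TestZip:
    def test_bliss_independent_grid_scores_zero(self):
        a, b = scenarios.synergy_plates(0)
        res = zip_delta(tf.generate_combination_grid(a, b, 0.0))
        assert abs(res.mean_delta) < 1.0
        assert res.interaction_class == "additive"

    def test_injected_deviation_recovered_and_synergistic(self):
        a, b = scenarios.synergy_plates(0)
        res = zip_delta(tf.generate_combination_grid(a, b, 0.15))
        assert 12.0 <= res.mean_delta <= 18.0
        assert res.interaction_class == "synergistic"

    def test_antagonistic_deviation(self):
        a, b = scenarios.synergy_plates(0)
        res = zip_delta(tf.generate_combination_grid(a, b, -0.15))
        assert res.mean_delta < -10.0
        assert res.interaction_class == "antagonistic"

    def test_transpose_symmetry(self):
        a, b = scenarios.synergy_plates(3)
        grid = tf.generate_combination_grid(a, b, 0.12)
        res = zip_delta(grid)
        res_t = zip_delta(grid.transpose())
        assert res.mean_delta == pytest.approx(res_t.mean_delta, abs=1e-6)

    def test_bliss_expectation_of_own_margins_scores_zero(self):
        # arbitrary logistic margins, interior set exactly to their Bliss product
        doses = np.array([0.0, 0.1, 0.3, 1.0, 3.0])
        ya = (doses / 0.5) ** 1.3 / (1 + (doses / 0.5) ** 1.3)
        yb = (doses / 0.8) ** 0.9 / (1 + (doses / 0.8) ** 0.9)
        grid = tf.CombinationGrid(doses, doses,
                                  ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :])
        assert abs(zip_delta(grid).mean_delta) < 1e-6

    def test_requires_three_nonzero_doses(self):
        doses = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="3 nonzero"):
            zip_delta(tf.CombinationGrid(doses, doses, np.zeros((3, 3))))


class TestPanelIC50s:
    def test_cell_type_panel_recovers_planted_sensitivities(self):
        panel = scenarios.plate_panel(seed=11)
        truth = {"sensitive": 0.35, "intermediate": 1.63, "insensitive": 101.63}
        for name, spec in panel.items():
            plate = tf.generate_dose_response_plate(spec)
            fit = fit_four_pl(plate["dose"].to_numpy(), plate["response"].to_numpy())
            ic50 = absolute_ic50(fit)
            assert ic50 == pytest.approx(truth[name], rel=0.2)
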