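"""Cumulative-incidence integrals, aggregation, bias RR, and table correction."""

import numpy as np
import pytest

from ltbca.core import (
    AgeStratum,
    DegenerateScenarioError,
    ModelOptions,
    StudyWindow,
    WindowError,
    aggregate_strata,
    bias_rr,
    correct_two_by_two,
    cum_incidence_unscreened,
    screening_parts,
    stratum_components,
)
from ltbca.duration import lognormal_from_mode_sd
from ltbca.scenario import compute_bias_for
from ltbca.screening import ScreeningBehavior, ScreeningPolicy


def const_intensity(c):
    def w(x):
        return np.full_like(np.asarray(x, dtype=float), c)
    return w


def flat_behavior(k1, k2, stratum="s", period="during"):
    return ScreeningBehavior(stratum=stratum, period=period,
                             edges=(0.0, 120.0), k1=(k1,), k2=(k2,))


WINDOW = StudyWindow(
    strata=(AgeStratum("60-64", 60.0, 65.0),),
    weights={"all": (1.0,)},
    screenage=40.0,
)
STRATUM = WINDOW.strata[0]


class TestUnscreened:
    def test_zero_intensity_gives_zero(self):
        f = lognormal_from_mode_sd(3, 3)
        w0 = const_intensity(0.0)
        assert cum_incidence_unscreened(w0, w0, f, WINDOW, STRATUM) == 0.0

    def test_near_point_mass_duration_closed_form(self):
        """With sojourn ~= exactly m years and constant onset intensity c, only
        onsets in (a0 - m, aE - m] produce in-window diagnoses, so
        G_U -> c * (aE - a0) when m < a0."""
        c, m = 1e-3, 3.0
        f = lognormal_from_mode_sd(m, 1e-3)
        w = const_intensity(c)
        g = cum_incidence_unscreened(w, w, f, WINDOW, STRATUM)
        assert g == pytest.approx(c * (STRATUM.aE - STRATUM.a0), rel=1e-4)


class TestScreeningParts:
    def test_zero_sensitivity_gives_zero_parts(self):
        f = lognormal_from_mode_sd(5, 3)
        w = const_intensity(1e-3)
        beh = flat_behavior(0.8, 1.0)
        policy = ScreeningPolicy(sensitivity=0.0, screenage=40.0)
        assert screening_parts(w, w, f, beh, beh, policy, WINDOW, STRATUM) == (0.0, 0.0, 0.0)

    def test_nobody_screening_gives_zero_parts(self):
        f = lognormal_from_mode_sd(5, 3)
        w = const_intensity(1e-3)
        beh = flat_behavior(0.0, 1.0)
        policy = ScreeningPolicy(sensitivity=0.86, screenage=40.0)
        assert screening_parts(w, w, f, beh, beh, policy, WINDOW, STRATUM) == (0.0, 0.0, 0.0)

    def test_gs_equals_gu_without_screening_bitwise(self):
        f = lognormal_from_mode_sd(5, 3)
        w = const_intensity(1e-3)
        beh = flat_behavior(0.5, 1.0)
        policy = ScreeningPolicy(sensitivity=0.0, screenage=40.0)
        comp = stratum_components(w, w, f, beh, beh, policy, WINDOW, STRATUM)
        assert comp.g_s == comp.g_u

    def test_prewindow_screening_only_removes_cases(self):
        """Screening only before the window eliminates cases (part3 > 0) and
        adds none, so G_S < G_U."""
        f = lognormal_from_mode_sd(5, 3)
        w = const_intensity(1e-3)
        beh_b = flat_behavior(0.8, 1.0, period="before")
        beh_d = flat_behavior(0.0, 0.0, period="during")
        policy = ScreeningPolicy(sensitivity=0.66, screenage=40.0)
        comp = stratum_components(w, w, f, beh_b, beh_d, policy, WINDOW, STRATUM)
        assert comp.part1 == 0.0 and comp.part2 == 0.0
        assert comp.part3 > 0.0
        assert comp.g_s < comp.g_u

    def test_literal_product_form_detects_less_in_part1(self):
        """The literal nested product requires pre-window screener status, so
        part1 can only shrink relative to the complement form."""
        f = lognormal_from_mode_sd(5, 3)
        w = const_intensity(1e-3)
        beh = flat_behavior(0.5, 0.5)
        policy = ScreeningPolicy(sensitivity=0.66, screenage=40.0)
        coupled = screening_parts(w, w, f, beh, beh, policy, WINDOW, STRATUM,
                                  ModelOptions(line1_form="coupled"))
        product = screening_parts(w, w, f, beh, beh, policy, WINDOW, STRATUM,
                                  ModelOptions(line1_form="product"))
        assert product[0] < coupled[0]
        assert product[1:] == coupled[1:]


def test_quadrature_stable_under_step_halving(inputs_biased):
    """Halving the integration step changes G_U and G_S by < 1e-6 relative."""
    beh_b = inputs_biased.behaviors[(inputs_biased.exposed, "before")]
    beh_d = inputs_biased.behaviors[(inputs_biased.exposed, "during")]
    for age_stratum in inputs_biased.window.strata:
        opts = ModelOptions(step=inputs_biased.options.step, refinement_check=True)
        stratum_components(
            inputs_biased.w_b, inputs_biased.w_d, inputs_biased.duration,
            beh_b, beh_d, inputs_biased.policy, inputs_biased.window,
            age_stratum, opts,
        )  # raises QuadratureError on drift > 1e-6


class TestAggregation:
    def test_single_stratum_identity(self):
        assert aggregate_strata([0.42], [1.0]) == 0.42

    def test_equal_values_pass_through(self):
        assert aggregate_strata([3.0, 3.0, 3.0], [0.2, 0.3, 0.5]) == pytest.approx(3.0)

    def test_weighted_mean(self):
        assert aggregate_strata([1, 2, 3, 4], [0.25] * 4) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(WindowError):
            aggregate_strata([1.0, 2.0], [1.0])


class TestBiasRR:
    def test_identical_strata_give_unity(self, inputs_null):
        result = compute_bias_for(inputs_null)
        assert result.rr == pytest.approx(1.0, abs=1e-12)

    def test_swapping_strata_inverts(self):
        assert bias_rr(2.0, 1.0) == pytest.approx(1.0 / bias_rr(1.0, 2.0))

    def test_zero_denominator_rejected(self):
        with pytest.raises(DegenerateScenarioError):
            bias_rr(1.0, 0.0)

    def test_differential_screening_inflates_rr(self, bias_biased):
        assert bias_biased.rr > 1.0


class TestCorrection:
    def test_unit_rr_changes_nothing(self):
        t = correct_two_by_two(120, 880, 100, 900, 1.0)
        assert t.corrected_odds_ratio == t.odds_ratio
        assert t.corrected_risk_ratio == t.risk_ratio

    def test_worked_example(self):
        t = correct_two_by_two(120, 880, 100, 900, 1.2)
        assert t.corrected_odds_ratio == pytest.approx(120 * 900 / (880 * 120), rel=1e-12)
        assert t.corrected_odds_ratio == pytest.approx(1.022727, abs=1e-6)

    def test_zero_cells_give_nan_not_exception(self):
        t = correct_two_by_two(0, 100, 0, 100, 1.2)
        assert np.isnan(t.odds_ratio) and np.isnan(t.corrected_odds_ratio)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DegenerateScenarioError):
            correct_two_by_two(-1, 2, 3, 4, 1.0)
        with pytest.raises(DegenerateScenarioError):
            correct_two_by_two(1, 2, 3, 4, 0.0)


class TestWindows:
    def test_degenerate_window_rejected(self):
        with pytest.raises(WindowError):
            AgeStratum("empty", 60.0, 60.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(WindowError):
            StudyWindow(
                strata=(AgeStratum("a", 55.0, 60.0), AgeStratum("b", 60.0, 65.0)),
                weights={"all": (0.6, 0.6)},
                screenage=40.0,
            )

    def test_window_cannot_exceed_maxage(self):
        with pytest.raises(WindowError):
            StudyWindow(
                strata=(AgeStratum("a", 90.0, 105.0),),
                weights={"all": (1.0,)},
                screenage=40.0,
                maxage=100.0,
            )
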