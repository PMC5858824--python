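"""Screening step functions, detection/escape probabilities, survey conversion."""

import numpy as np
import pytest

from ltbca.screening import (
    IntervalError,
    ScreeningBehavior,
    ScreeningDataError,
    ScreeningPolicy,
    SurveyBin,
    behavior_from_survey,
    detection_probability,
    expected_screens,
)


def behavior(edges, k1, k2, stratum="s", period="during"):
    return ScreeningBehavior(stratum=stratum, period=period,
                             edges=edges, k1=k1, k2=k2)


@pytest.fixture
def flat():
    return behavior((50.0, 60.0), (1.0,), (1.0,))


@pytest.fixture
def piecewise():
    return behavior((50.0, 55.0, 60.0), (0.6, 0.8), (0.5, 1.0))


class TestExpectedScreens:
    def test_constant_rate(self, flat):
        assert expected_screens(flat, 52.0, 55.0) == pytest.approx(3.0)

    def test_empty_interval(self, flat):
        assert expected_screens(flat, 54.0, 54.0) == 0.0

    def test_piecewise_overlap_sum(self, piecewise):
        # 3y at 0.5/yr plus 3y at 1.0/yr
        assert expected_screens(piecewise, 52.0, 58.0) == pytest.approx(4.5)

    def test_nearest_bin_extrapolation(self, piecewise):
        # below the bins the first rate extends; above, the last rate
        assert expected_screens(piecewise, 48.0, 50.0) == pytest.approx(1.0)
        assert expected_screens(piecewise, 60.0, 62.0) == pytest.approx(2.0)

    def test_reversed_interval_rejected(self, flat):
        with pytest.raises(IntervalError):
            expected_screens(flat, 55.0, 52.0)

    def test_exponent_additivity(self, piecewise):
        n_uv = expected_screens(piecewise, 51.0, 54.0)
        n_vw = expected_screens(piecewise, 54.0, 59.0)
        n_uw = expected_screens(piecewise, 51.0, 59.0)
        xi = 0.46
        assert (1 - xi) ** n_uv * (1 - xi) ** n_vw == pytest.approx((1 - xi) ** n_uw)


class TestDetectionProbability:
    def test_perfect_sensitivity_detects_at_first_screen(self, flat):
        policy = ScreeningPolicy(sensitivity=1.0, screenage=50.0)
        p = detection_probability(flat, policy, 50.0, 50.0, 55.0)
        assert p == pytest.approx(flat.k1_at(50.0))

    def test_single_screen_at_test_sensitivity(self, flat):
        policy = ScreeningPolicy(sensitivity=0.46, screenage=50.0)
        # one expected screen in [54, 55): detection = k1 * xi
        assert detection_probability(flat, policy, 40.0, 54.0, 55.0) == pytest.approx(0.46)

    def test_no_screens_before_screenage(self, flat):
        policy = ScreeningPolicy(sensitivity=0.86, screenage=58.0)
        assert detection_probability(flat, policy, 40.0, 50.0, 58.0) == 0.0

    def test_onset_truncates_interval(self, flat):
        policy = ScreeningPolicy(sensitivity=0.46, screenage=50.0)
        # onset at 53 - screens in [50, 53) cannot detect
        p_late_onset = detection_probability(flat, policy, 53.0, 50.0, 55.0)
        assert p_late_onset == pytest.approx(1 - (1 - 0.46) ** 2)

    def test_monotone_in_interval_sensitivity_and_rate(self, piecewise):
        ages_v = np.linspace(51.0, 60.0, 19)
        policy = ScreeningPolicy(sensitivity=0.46, screenage=50.0)
        p = [detection_probability(piecewise, policy, 50.0, 50.0, v) for v in ages_v]
        assert np.all(np.diff(p) >= -1e-15)
        for lo, hi in [(0.2, 0.46), (0.46, 0.86)]:
            p_lo = detection_probability(piecewise, ScreeningPolicy(lo, 50.0), 50.0, 50.0, 58.0)
            p_hi = detection_probability(piecewise, ScreeningPolicy(hi, 50.0), 50.0, 50.0, 58.0)
            assert p_hi > p_lo
        denser = behavior((50.0, 55.0, 60.0), (0.6, 0.8), (1.0, 2.0))
        assert detection_probability(denser, policy, 50.0, 50.0, 58.0) > \
            detection_probability(piecewise, policy, 50.0, 50.0, 58.0)

    def test_result_bounded_by_k1(self, piecewise):
        policy = ScreeningPolicy(sensitivity=0.86, screenage=40.0)
        for x in (50.0, 54.0, 57.0):
            p = detection_probability(piecewise, policy, x, 40.0, 80.0)
            assert 0.0 <= p <= piecewise.k1_at(x)

    def test_linear_form_is_clamped(self, flat):
        policy = ScreeningPolicy(sensitivity=0.46, screenage=50.0,
                                 detection_form="linear")
        # 5 expected screens -> 0.46 * 5 > 1 clamps to k1
        assert detection_probability(flat, policy, 40.0, 50.0, 55.0) == pytest.approx(1.0)
        assert detection_probability(flat, policy, 40.0, 54.0, 55.0) == pytest.approx(0.46)


class TestValidation:
    def test_bad_step_functions_rejected(self):
        with pytest.raises(ScreeningDataError):
            behavior((50.0, 60.0), (1.2,), (1.0,))
        with pytest.raises(ScreeningDataError):
            behavior((50.0, 60.0), (0.5,), (-1.0,))
        with pytest.raises(ScreeningDataError):
            behavior((60.0, 50.0), (0.5,), (1.0,))
        with pytest.raises(ScreeningDataError):
            ScreeningPolicy(sensitivity=1.3, screenage=50.0)


class TestSurveyConversion:
    def test_counts_to_rates_arithmetic(self):
        bins = [SurveyBin(55.0, 60.0, n_total=100, n_screened_1=30,
                          n_screened_2plus=10, window_years=3.0)]
        beh = behavior_from_survey(bins, "s", "before")
        assert beh.k1 == (0.4,)
        assert beh.k2[0] == pytest.approx((30 + 2 * 10) / (40 * 3.0))

    def test_nobody_screened_gives_zero_rates(self):
        bins = [SurveyBin(55.0, 60.0, 50, 0, 0, 3.0)]
        beh = behavior_from_survey(bins, "s", "before")
        assert beh.k1 == (0.0,) and beh.k2 == (0.0,)

    def test_impossible_counts_rejected(self):
        bins = [SurveyBin(55.0, 60.0, 20, 15, 10, 3.0)]
        with pytest.raises(ScreeningDataError):
            behavior_from_survey(bins, "s", "before")

    def test_empty_bins_dropped_with_warning(self, caplog):
        bins = [
            SurveyBin(50.0, 55.0, 0, 0, 0, 3.0),
            SurveyBin(55.0, 60.0, 100, 30, 10, 3.0),
        ]
        with caplog.at_level("WARNING"):
            beh = behavior_from_survey(bins, "s", "before")
        assert beh.edges == (55.0, 60.0)
        assert "dropping empty survey bin" in caplog.text

    def test_two_plus_imputation_configurable(self):
        bins = [SurveyBin(55.0, 60.0, 100, 30, 10, 3.0)]
        beh = behavior_from_survey(bins, "s", "before", two_plus_value=3.0)
        assert beh.k2[0] == pytest.approx((30 + 3 * 10) / (40 * 3.0))
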