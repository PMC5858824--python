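"""Monte Carlo microsimulation: determinism, conservation, oracle agreement."""

import numpy as np
import pytest

from ltbca.core import correct_two_by_two
from ltbca.microsim import (
    ScenarioScalingError,
    realized_overdiagnosis,
    simulate_cohort,
    tabulate_two_by_two,
)
from ltbca.scenario import compute_bias_for


def run_sim(inputs, n, seed, **kw):
    return simulate_cohort(
        inputs.w_b, inputs.w_d, inputs.duration, inputs.behaviors,
        inputs.policy, inputs.window, [inputs.exposed, inputs.reference],
        n=n, seed=seed, **kw,
    )


def test_fixed_seed_reproduces_counts_exactly(inputs_biased):
    c1 = run_sim(inputs_biased, 5000, seed=11)
    c2 = run_sim(inputs_biased, 5000, seed=11)
    assert c1.cohorts == c2.cohorts


def test_zero_sensitivity_keeps_factual_equal_counterfactual(inputs_biased):
    zeroed = inputs_biased.with_policy(
        type(inputs_biased.policy)(sensitivity=0.0, screenage=40.0)
    )
    counts = run_sim(zeroed, 20000, seed=3)
    for c in counts.cohorts.values():
        assert c.screen_detected_in_window == 0
        assert c.pre_window_detected == 0
        assert c.factual_in_window == c.counterfactual_in_window


def test_class_counts_conserve_population(inputs_biased):
    counts = run_sim(inputs_biased, 10, seed=5)
    for c in counts.cohorts.values():
        assert c.factual_in_window + c.pre_window_detected + c.never_case == c.n
        assert c.n_onset <= c.n


def test_two_by_two_cells_sum_to_population(inputs_biased):
    counts = run_sim(inputs_biased, 10, seed=5)
    a, b, c, d = tabulate_two_by_two(
        counts, inputs_biased.exposed, inputs_biased.reference, inputs_biased.window
    )
    n_cohorts = len(inputs_biased.window.strata)
    assert a + b == 10 * n_cohorts
    assert c + d == 10 * n_cohorts


def test_symmetric_strata_give_null_odds_ratio(inputs_null):
    counts = run_sim(inputs_null, 100_000, seed=7)
    a, b, c, d = tabulate_two_by_two(
        counts, inputs_null.exposed, inputs_null.reference, inputs_null.window
    )
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert abs(log_or) < 3 * se


def test_poisson_screen_process_runs_and_detects_less(inputs_biased):
    """The Poisson-screens reading has escape exp(-xi*N) >= (1-xi)^N, so it
    detects (weakly) fewer cases in expectation."""
    geo = run_sim(inputs_biased, 100_000, seed=9)
    poi = run_sim(inputs_biased, 100_000, seed=9, screen_process="poisson")
    det_geo = sum(c.screen_detected_in_window + c.pre_window_detected
                  for c in geo.cohorts.values())
    det_poi = sum(c.screen_detected_in_window + c.pre_window_detected
                  for c in poi.cohorts.values())
    assert det_poi < det_geo


def test_onset_probability_guard(inputs_biased):
    def huge(x):
        return np.full_like(np.asarray(x, dtype=float), 0.5)

    with pytest.raises(ScenarioScalingError):
        simulate_cohort(
            huge, huge, inputs_biased.duration, inputs_biased.behaviors,
            inputs_biased.policy, inputs_biased.window,
            [inputs_biased.exposed, inputs_biased.reference], n=10, seed=1,
        )


def test_overdiagnosis_requires_mixture(inputs_biased):
    counts = run_sim(inputs_biased, 100, seed=1)
    with pytest.raises(ValueError):
        realized_overdiagnosis(counts)


def test_cohort_proportions_match_analytic_model(inputs_biased):
    """Spot oracle check at moderate n (the full 3-SE sweep runs in the
    acceptance suite): aggregated G_U and G_S within 3 MC SE."""
    res = compute_bias_for(inputs_biased)
    counts = run_sim(inputs_biased, 50_000, seed=13)
    for stratum in (inputs_biased.exposed, inputs_biased.reference):
        for agg_key, attr in [("G_U", "counterfactual_in_window"), ("G_S", "gs_count")]:
            est, se = counts.aggregate(inputs_biased.window, stratum, attr)
            assert abs(res.aggregated[stratum][agg_key] - est) < 3 * se


def test_end_to_end_null_recovery(inputs_biased):
    """Correcting the simulated biased 2x2 with the analytic RR recovers a
    null odds ratio within Monte Carlo error."""
    res = compute_bias_for(inputs_biased)
    counts = run_sim(inputs_biased, 100_000, seed=17)
    a, b, c, d = tabulate_two_by_two(
        counts, inputs_biased.exposed, inputs_biased.reference, inputs_biased.window
    )
    table = correct_two_by_two(a, b, c, d, res.rr)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert table.odds_ratio > 1.0
    assert abs(np.log(table.corrected_odds_ratio)) < 3 * se
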