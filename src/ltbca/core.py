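"""Cumulative-incidence integrals and the lead-time bias relative risk.

For each risk-factor stratum ``r`` and age stratum ``i`` with study window
``[a0, aE]`` the model evaluates:

* ``G_U`` — counterfactual cumulative incidence with nobody screened:
  preclinical onset at any age ``x`` in ``[0, aE]`` (intensity ``w_b`` before
  enrollment, ``w_d`` during) whose symptomatic diagnosis ``z = x + t`` falls
  inside the window, i.e. the sojourn CDF difference ``F(aE-x) - F(a0-x)``;

* three screening terms:

  - *part1*: onset before the window, escapes pre-window screening, is
    screen-detected during the window, and counterfactually would have been
    diagnosed only after the window (``z`` in ``(aE, maxage]``) — cases
    *added* by screening;
  - *part2*: as part1 but onset during the window — also added;
  - *part3*: onset before the window and screen-detected before it, but
    counterfactually diagnosed inside the window — cases *removed*;

* ``G_S = G_U + part1 + part2 - part3`` — the cumulative incidence actually
  ascertained under the stratum's screening behavior.

Age strata are combined with population weights ``omega`` and the bias
relative risk is ``RR = G_S(exposed) / G_S(reference)``; 1 means no
lead-time-biased case-ascertainment. Multiplying the reference-stratum case
count of an observed 2x2 table by this RR de-biases the odds/risk ratio.

Integration is composite Simpson on a uniform age grid (default step 0.05
years) split at the integrand's known kink points (screening-bin edges,
``screenage``), with the inner sojourn integral collapsed to a CDF
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duration import DurationSpec
from .incidence import IncidenceCurve
from .screening import ScreeningBehavior, ScreeningPolicy, escape_probability, expected_screens

__all__ = [
    "AgeStratum",
    "StudyWindow",
    "ModelOptions",
    "StratumResult",
    "BiasResult",
    "cum_incidence_unscreened",
    "screening_parts",
    "cum_incidence_observed",
    "stratum_components",
    "aggregate_strata",
    "bias_rr",
    "correct_two_by_two",
    "compute_bias",
]


class WindowError(ValueError):
    """Raised for invalid or degenerate study windows."""


class ModelInconsistencyError(RuntimeError):
    """Raised when G_S is numerically negative beyond tolerance."""


class DegenerateScenarioError(ValueError):
    """Raised when a ratio is requested with a zero denominator."""


class QuadratureError(RuntimeError):
    """Raised when step refinement does not confirm the quadrature."""


@dataclass(frozen=True)
class AgeStratum:
    """One enrollment age band: window ``[a0, aE]`` of case ascertainment."""

    label: str
    a0: float
    aE: float

    def __post_init__(self):
        if not self.a0 < self.aE:
            raise WindowError(
                f"age stratum {self.label!r}: need a0 < aE, got [{self.a0}, {self.aE}]"
            )


@dataclass(frozen=True)
class StudyWindow:
    """Study windows per age stratum plus global screening/horizon ages.

    ``weights`` maps risk-stratum label -> per-age-stratum weights; the key
    ``"all"`` provides shared weights for any stratum without its own entry.
    """

    strata: tuple[AgeStratum, ...]
    weights: dict[str, tuple[float, ...]]
    screenage: float
    maxage: float = 100.0

    def __post_init__(self):
        for s in self.strata:
            if s.aE > self.maxage:
                raise WindowError(
                    f"age stratum {s.label!r}: aE={s.aE} exceeds maxage={self.maxage}"
                )
        for key, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(self.strata):
                raise WindowError(
                    f"weights[{key!r}]: {len(w)} values for {len(self.strata)} age strata"
                )
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
                raise WindowError(f"weights[{key!r}] must be >= 0 and sum to 1")

    def weights_for(self, stratum: str) -> np.ndarray:
        if stratum in self.weights:
            return np.asarray(self.weights[stratum], dtype=float)
        if "all" in self.weights:
            return np.asarray(self.weights["all"], dtype=float)
        raise WindowError(f"no weights for stratum {stratum!r} and no 'all' entry")


@dataclass(frozen=True)
class ModelOptions:
    """Switches of the analytic model.

    ``line1_form``: how the pre-window escape factor of part1 combines with
    the in-window detection factor. ``"coupled"`` (default) treats the
    before- and during-period screener indicators as independent Bernoulli
    draws, so non-screeners escape with probability 1:
    ``[1 - k_b1 (1 - esc_b)] * k_d1 (1 - esc_d)``. ``"product"`` is the
    literal nested product ``k_b1 esc_b * k_d1 (1 - esc_d)``, which demands
    pre-window screener status.

    ``gs_includes_baseline``: if False, ``G_S`` is only the screening delta
    ``part1 + part2 - part3`` rather than ``G_U`` plus the delta.
    """

    step: float = 0.05
    line1_form: str = "coupled"
    gs_includes_baseline: bool = True
    refinement_check: bool = False
    refinement_rtol: float = 1e-6

    def __post_init__(self):
        if self.step <= 0:
            raise WindowError(f"quadrature step must be > 0, got {self.step}")
        if self.line1_form not in ("coupled", "product"):
            raise WindowError(f"line1_form must be 'coupled' or 'product'")


def _simpson_piece(f, a: float, b: float, step: float) -> float:
    """Composite Simpson on one smooth piece with an even node count."""
    if b <= a:
        return 0.0
    n = max(2, int(np.ceil((b - a) / step)))
    if n % 2:
        n += 1
    x = np.linspace(a, b, n + 1)
    # evaluate one-sided limits at the piece ends so that step-function
    # factors (k1, k2 bins) take the value of THIS piece at its boundary
    x[0] = np.nextafter(a, b)
    x[-1] = np.nextafter(b, a)
    y = f(x)
    h = (b - a) / n
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return float(h / 3.0 * np.dot(w, y))


def _integrate(f, a: float, b: float, step: float, breaks=()) -> float:
    """Simpson over [a, b], split at interior breakpoints where f has kinks."""
    if b <= a:
        return 0.0
    pts = sorted({a, b, *(p for p in breaks if a < p < b)})
    return sum(_simpson_piece(f, lo, hi, step) for lo, hi in zip(pts[:-1], pts[1:]))


def _kinks(*behaviors: ScreeningBehavior, screenage: float) -> tuple[float, ...]:
    pts = {screenage}
    for beh in behaviors:
        pts.update(beh.breakpoints)
    return tuple(sorted(pts))


def cum_incidence_unscreened(
    w_b: IncidenceCurve,
    w_d: IncidenceCurve,
    f: DurationSpec,
    window: StudyWindow,
    stratum: AgeStratum,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Counterfactual (never-screened) cumulative incidence over the window."""
    a0, aE = stratum.a0, stratum.aE

    def before(x):
        return w_b(x) * (f.cdf(aE - x) - f.cdf(a0 - x))

    def during(x):
        return w_d(x) * f.cdf(aE - x)

    g = _integrate(before, 0.0, a0, options.step)
    g += _integrate(during, a0, aE, options.step)
    return g


def screening_parts(
    w_b: IncidenceCurve,
    w_d: IncidenceCurve,
    f: DurationSpec,
    behavior_b: ScreeningBehavior,
    behavior_d: ScreeningBehavior,
    policy: ScreeningPolicy,
    window: StudyWindow,
    stratum: AgeStratum,
    options: ModelOptions = ModelOptions(),
) -> tuple[float, float, float]:
    """The three screening terms (added, added, removed) for one age stratum."""
    a0, aE = stratum.a0, stratum.aE
    sa, maxage = window.screenage, window.maxage
    kinks = _kinks(behavior_b, behavior_d, screenage=sa)

    def esc_before(x):
        lo = np.minimum(np.maximum(x, sa), a0)
        n = expected_screens(behavior_b, lo, np.full_like(np.asarray(x, float), a0))
        return escape_probability(policy, n)

    def det_during(x):
        lo = np.minimum(np.maximum(np.maximum(x, sa), a0), aE)
        n = expected_screens(behavior_d, lo, np.full_like(np.asarray(x, float), aE))
        return 1.0 - escape_probability(policy, n)

    def integrand1(x):
        tail = f.cdf(maxage - x) - f.cdf(aE - x)
        k_b1 = behavior_b.k1_at(x)
        k_d1 = behavior_d.k1_at(x)
        if options.line1_form == "coupled":
            escape = 1.0 - k_b1 * (1.0 - esc_before(x))
        else:
            escape = k_b1 * esc_before(x)
        return w_b(x) * escape * k_d1 * det_during(x) * tail

    def integrand2(x):
        tail = f.cdf(maxage - x) - f.cdf(aE - x)
        return w_d(x) * behavior_d.k1_at(x) * det_during(x) * tail

    def integrand3(x):
        in_window = f.cdf(aE - x) - f.cdf(a0 - x)
        return w_b(x) * behavior_b.k1_at(x) * (1.0 - esc_before(x)) * in_window

    part1 = _integrate(integrand1, 0.0, a0, options.step, kinks)
    part2 = _integrate(integrand2, a0, aE, options.step, kinks)
    part3 = _integrate(integrand3, 0.0, a0, options.step, kinks)
    return part1, part2, part3


def cum_incidence_observed(
    w_b: IncidenceCurve,
    w_d: IncidenceCurve,
    f: DurationSpec,
    behavior_b: ScreeningBehavior,
    behavior_d: ScreeningBehavior,
    policy: ScreeningPolicy,
    window: StudyWindow,
    stratum: AgeStratum,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Screening-adjusted cumulative incidence ``G_S`` for one age stratum."""
    comp = stratum_components(
        w_b, w_d, f, behavior_b, behavior_d, policy, window, stratum, options
    )
    return comp.g_s


@dataclass(frozen=True)
class StratumResult:
    """All components for one (risk stratum, age stratum) cell."""

    stratum: str
    age_stratum: str
    g_u: float
    part1: float
    part2: float
    part3: float
    g_s: float


def stratum_components(
    w_b, w_d, f, behavior_b, behavior_d, policy, window, stratum,
    options: ModelOptions = ModelOptions(),
) -> StratumResult:
    g_u = cum_incidence_unscreened(w_b, w_d, f, window, stratum, options)
    p1, p2, p3 = screening_parts(
        w_b, w_d, f, behavior_b, behavior_d, policy, window, stratum, options
    )
    if options.gs_includes_baseline:
        g_s = g_u + p1 + p2 - p3
    else:
        g_s = p1 + p2 - p3
    if g_s < -1e-9:
        raise ModelInconsistencyError(
            f"G_S = {g_s} < 0 for stratum {behavior_d.stratum!r}, "
            f"age stratum {stratum.label!r}"
        )
    if options.refinement_check:
        fine = ModelOptions(
            step=options.step / 2.0,
            line1_form=options.line1_form,
            gs_includes_baseline=options.gs_includes_baseline,
        )
        g_u2 = cum_incidence_unscreened(w_b, w_d, f, window, stratum, fine)
        q1, q2, q3 = screening_parts(
            w_b, w_d, f, behavior_b, behavior_d, policy, window, stratum, fine
        )
        g_s2 = (g_u2 if options.gs_includes_baseline else 0.0) + q1 + q2 - q3
        scale = max(abs(g_u), abs(g_s), 1e-12)
        err = max(abs(g_u - g_u2), abs(g_s - g_s2)) / scale
        if err > options.refinement_rtol:
            raise QuadratureError(
                f"halving the step changed the result by {err:.2e} relative "
                f"(> {options.refinement_rtol:.0e}); achieved tolerance {err:.2e}"
            )
    return StratumResult(
        stratum=behavior_d.stratum,
        age_stratum=stratum.label,
        g_u=g_u, part1=p1, part2=p2, part3=p3, g_s=max(g_s, 0.0),
    )


def aggregate_strata(values, weights) -> float:
    """Population-weighted sum ``sum_i omega_i * value_i`` over age strata."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise WindowError(
            f"{len(values)} values for {len(weights)} weights"
        )
    return float(np.dot(weights, values))


def bias_rr(g_s_exposed: float, g_s_reference: float) -> float:
    """Bias relative risk ``G_S(exposed) / G_S(reference)``; 1 = unbiased."""
    if g_s_reference <= 0.0 or g_s_exposed < 0.0:
        raise DegenerateScenarioError(
            f"bias RR undefined for G_S exposed={g_s_exposed}, "
            f"reference={g_s_reference}"
        )
    return g_s_exposed / g_s_reference


@dataclass(frozen=True)
class CorrectedTable:
    """Uncorrected and bias-corrected OR/RR from a 2x2 table.

    ``a``: exposed cases, ``b``: exposed noncases, ``c``: unexposed cases,
    ``d``: unexposed noncases. The correction multiplies ``c`` by the
    simulated bias RR; undefined estimates (zero cells) are NaN.
    """

    a: float
    b: float
    c: float
    d: float
    rr_bias: float
    odds_ratio: float
    risk_ratio: float
    corrected_odds_ratio: float
    corrected_risk_ratio: float


def _safe_or(a, b, c, d) -> float:
    return a * d / (b * c) if b > 0 and c > 0 else float("nan")


def _safe_rr(a, b, c, d) -> float:
    if a + b == 0 or c + d == 0 or c == 0:
        return float("nan")
    return (a / (a + b)) / (c / (c + d))


def correct_two_by_two(a, b, c, d, rr: float) -> CorrectedTable:
    """De-bias an observed 2x2 table with the simulated bias RR.

    Inflating the unexposed case count ``c`` to ``c * rr`` equalizes the
    expected ascertainment rates between strata under the null, so the
    corrected OR/RR estimate the screening-free association.
    """
    if min(a, b, c, d) < 0:
        raise DegenerateScenarioError("2x2 counts must be nonnegative")
    if not rr > 0:
        raise DegenerateScenarioError(f"bias RR must be > 0, got {rr}")
    c_adj = c * rr
    return CorrectedTable(
        a=a, b=b, c=c, d=d, rr_bias=rr,
        odds_ratio=_safe_or(a, b, c, d),
        risk_ratio=_safe_rr(a, b, c, d),
        corrected_odds_ratio=_safe_or(a, b, c_adj, d),
        corrected_risk_ratio=_safe_rr(a, b, c_adj, d),
    )


@dataclass(frozen=True)
class BiasResult:
    """Per-cell components, per-stratum aggregates, and the bias RR."""

    cells: tuple[StratumResult, ...]
    aggregated: dict[str, dict[str, float]]  # stratum -> {"G_U": ..., "G_S": ...}
    exposed: str
    reference: str
    rr: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": c.stratum, "age_stratum": c.age_stratum,
                "G_U": c.g_u, "part1": c.part1, "part2": c.part2,
                "part3": c.part3, "G_S": c.g_s,
            }
            for c in self.cells
        ]
        for stratum, agg in self.aggregated.items():
            rows.append({
                "stratum": stratum, "age_stratum": "aggregate",
                "G_U": agg["G_U"], "part1": agg["part1"], "part2": agg["part2"],
                "part3": agg["part3"], "G_S": agg["G_S"],
            })
        df = pd.DataFrame(rows)
        df["rr"] = np.nan
        summary = pd.DataFrame([{
            "stratum": f"{self.exposed}/{self.reference}",
            "age_stratum": "summary", "G_U": np.nan, "part1": np.nan,
            "part2": np.nan, "part3": np.nan, "G_S": np.nan, "rr": self.rr,
        }])
        return pd.concat([df, summary], ignore_index=True)


def compute_bias(
    w_b: IncidenceCurve,
    w_d: IncidenceCurve,
    f: DurationSpec,
    behaviors: dict[tuple[str, str], ScreeningBehavior],
    policy: ScreeningPolicy,
    window: StudyWindow,
    exposed: str,
    reference: str,
    options: ModelOptions = ModelOptions(),
) -> BiasResult:
    """Evaluate all cells for two risk strata and form the bias RR.

    ``behaviors`` maps ``(stratum, period)`` with period in
    ``{"before", "during"}``.
    """
    cells: list[StratumResult] = []
    aggregated: dict[str, dict[str, float]] = {}
    for stratum in (exposed, reference):
        beh_b = behaviors[(stratum, "before")]
        beh_d = behaviors[(stratum, "during")]
        omega = window.weights_for(stratum)
        per_age = [
            stratum_components(
                w_b, w_d, f, beh_b, beh_d, policy, window, age_stratum, options
            )
            for age_stratum in window.strata
        ]
        cells.extend(per_age)
        aggregated[stratum] = {
            key: aggregate_strata([getattr(c, attr) for c in per_age], omega)
            for key, attr in [
                ("G_U", "g_u"), ("part1", "part1"), ("part2", "part2"),
                ("part3", "part3"), ("G_S", "g_s"),
            ]
        }
    rr = bias_rr(aggregated[exposed]["G_S"], aggregated[reference]["G_S"])
    return BiasResult(
        cells=tuple(cells), aggregated=aggregated,
        exposed=exposed, reference=reference, rr=rr,
    )
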