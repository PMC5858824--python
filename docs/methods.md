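# Methods

## Model and assumptions

`ltbca` implements a progressive-disease, counterfactual model of
lead-time-biased case-ascertainment (LTBCA). Each individual passes through
detectable preclinical onset (age *x*) to symptomatic diagnosis
(*z = x + t*). The model assumes:

- neither the risk factor nor screening alters underlying disease
  incidence or mortality (the joint null), so any departure of the
  cross-stratum ratio from 1 is bias;
- disease is progressive: nobody regresses out of the preclinical state;
- the sojourn distribution is age-invariant within a scenario;
- screening behavior is adequately summarized by two age-step functions
  per stratum and period — the proportion ever screening *k₁(x)*, read at
  the onset age, and the screening rate among screeners *k₂(x)* — with
  per-period screener status drawn independently;
- per-screen sensitivity ξ is constant, and screens are conditionally
  independent given the expected count, giving the geometric escape law
  (1 − ξ)^N with N = ∫k₂;
- no competing mortality and no calendar-time bookkeeping beyond the
  before/during split of the incidence and screening functions.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| sojourn mode | years | 5 | typical preclinical duration; grid 1, 3, 5, 10 |
| sojourn sd | years | 3 | sojourn spread; grid 1, 3, 5 |
| overdiagnosis weight | — | 0 (0.2 when on) | mass on the long component (mode 20 y, sd 3 y) |
| sensitivity ξ | — | 0.46 | per-screen detection probability; grid 0.46, 0.66, 0.86 |
| screenage | years | 40 | age screening can begin for screeners |
| maxage | years | 100 | horizon for "would ever surface clinically" |
| study windows | years | [55,60) … [70,75) | four 5-year enrollment strata, 5-year ascertainment |
| age-stratum weights ω | — | uniform 0.25 | enrollment age structure; `trial-like` and stratum-specific options |
| quadrature step | years | 0.05 | Simpson grid spacing |

The sojourn lognormal is parameterized by (mode, sd): substituting the mode
identity μ = log(mode) + σ² into the variance identity leaves one monotone
equation in σ², solved by bracketed Brent iteration to 1e-10 and verified
by a round-trip check at construction.

## Incidence fitting and the back-shift

Registry-style inputs are band-averaged rates per 100,000 person-years.
The default family is the exponential of a cubic polynomial in age, fitted
by least squares on the log-rate scale at band midpoints (the final
open-ended band is anchored at its lower edge + 2.5 y). This family is
strictly positive and reproduces the convex midlife rise and late plateau
of adult cancer incidence with four parameters. Because neither the
functional family nor the fitting scale is canonical, both are exposed in
the scenario (`logquad` and a monotone PCHIP spline; raw-rate nonlinear
least squares seeded by the log fit). Rates are converted to per-person-year
intensities exactly once, at fit time. The preclinical onset intensity is
the fitted clinical curve shifted backward by the *mean* sojourn,
w(x) = curve(x + mean), clamped at `maxage`.

## The screening-adjusted incidence

The printed form of the three screening terms nests the before- and
during-period factors ambiguously, so both readings are implemented. The
default (`line1_form: coupled`) treats per-period screener status as
independent Bernoulli draws; a non-screener escapes pre-window detection
with probability 1, so part1's escape factor is
1 − k_b1(x)[1 − (1−ξ)^{N_b}]. The literal nested product
(`line1_form: product`), k_b1(x)(1−ξ)^{N_b}, demands pre-window screener
status and is retained for comparison. Detection integrals start at
max(onset age, screenage, interval start): a person cannot be screen-
detected before having detectable disease. G_S is defined as
G_U + part1 + part2 − part3 (`gs_includes_baseline: true`), so the
no-screening limit returns G_U exactly and equal behavior in both strata
gives RR = 1 identically; the delta-only reading is available as a switch.

A `linear` detection form, k₁·min(1, ξ′N), is provided as a clamped
alternative to the geometric law; whether ξ′ should be ξ or its complement
is not determinable from the construction, so it defaults to ξ.

## Numerical choices

- Composite Simpson on a uniform grid (step 0.05 y), with the integration
  range split at every knot where the integrand can kink or jump:
  screening-bin edges and `screenage`. Piece endpoints are evaluated one
  ulp inside the piece so step-function factors take their one-sided
  limits; without this the k₁ jumps degrade convergence to O(h).
  With it, halving the step changes G_U and G_S by ≲1e-9 relative on the
  default scenarios (a `refinement_check` switch enforces 1e-6).
- The inner sojourn integral is collapsed to a CDF difference
  (F(b−x) − F(a−x)), removing one quadrature dimension.
- Expected screen counts over an interval are computed exactly for step
  functions via a cumulative piecewise-linear primitive, with nearest-bin
  constant extrapolation outside the observed bins.
- Degenerate inputs: a₀ = a_E windows, non-summing weights, ξ outside
  [0, 1], and onset intensities integrating to ≥ 1 per lifetime are
  rejected with specific errors; a numerically negative G_S beyond 1e-9 is
  a model-inconsistency error.

## Microsimulation oracle

The microsimulation draws, per person: onset (Bernoulli with probability
∫w over [0, a_E], age by inverse CDF on a 0.05-y grid), sojourn (with a
component tag under a mixture), per-period screener flags, and detection
before/during the window, truncating screening exposure at symptomatic
diagnosis. Factual and counterfactual outcomes are recorded for the same
person, so each analytic term corresponds to a disjoint person class and
binomial standard errors apply.

Two screen processes are available. The default `expected_count` draws the
detection indicator directly from the geometric escape law (1 − ξ)^N, the
same estimand the integrals use — so oracle comparisons isolate
integration and bookkeeping errors. The `poisson` option draws a Poisson
screen count with mean N with independent per-screen detection; its
expected escape is e^{−ξN} ≥ (1 − ξ)^N, the continuous-rate reading of the
same expected-count bracket. The two options bracket a genuine modelling
ambiguity; only `expected_count` is expected to agree with the analytic
model within Monte Carlo error.

Per-cohort random streams derive from the master seed and the cohort index,
so results do not depend on evaluation order.

## Realized overdiagnosis

Under the mixture, an individual is overdiagnosed if they carry the
long-sojourn component *and* are ever screen-detected. The realized rate is
reported among individuals who develop preclinical disease; in the
saturating limit (ξ = 1, universal annual screening from birth) it
approaches the nominal mixture weight, and with imperfect screening it
falls below it — the product of the detection probability and the nominal
rate. At the default biased conditions with ξ = 0.46 it is roughly 8%
versus the nominal 20%.

## What the synthetic inputs emulate — and what they do not

The fixture generator reproduces the *structure* of the real inputs: 5-year
registry bands for two calendar periods generated from a known log-cubic
truth (optionally with multiplicative noise), screening step functions with
a configurable during-study differential between strata (presets `null`,
`biased`, `intervention-like` with differential 0, 0.5, 1), and weights
summing to 1 per stratum. They do not reproduce any real population's
screening levels, which are only available as plots in the source
literature; consequently, passing tests demonstrate internal correctness
and qualitative behavior (null invariance, monotone growth of bias with
sojourn mode, dilution of overdiagnosis by imperfect sensitivity), not
quantitative agreement with any published table.

Default fixture levels were chosen once as plausible for chest-x-ray-style
screening: background screening k₁ ≈ 0.2–0.3 at one screen per 3 years
before the study in both strata; during the study k₁ ≈ 0.3–0.4 at 0.5/y in
the reference stratum, lifted toward k₁ ≈ 0.85–0.9 at 1/y in the exposed
stratum by the differential. `screenage` = 40 reflects screening being
available well before the enrollment ages.

## Problem sizes

The analytic model is deterministic and runs in well under a second per
scenario. Oracle comparisons and 2×2 studies use 200,000 persons per
(risk stratum × age stratum) cohort — binomial SEs near 3·10⁻⁴ on the
cumulative-incidence scale — and the full sensitivity grid is 72 analytic
cells.

## Known limitations

- Screening intensity abstracts scheduled trial rounds into a smooth rate;
  protocol-driven clustering of screens is not represented.
- No competing mortality: individuals cannot die before their
  (counterfactual) diagnosis, which overstates ascertainment slightly at
  the oldest ages.
- The sojourn distribution is shared across ages and strata; age-specific
  sojourns would require an (x, t) product model.
- The before/during split captures calendar drift in incidence and
  screening only as two averaged regimes.
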