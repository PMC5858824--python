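"""Synthetic study inputs: registry-style incidence, screening behavior,
and age-stratum weights.

These generators emulate the *structure* of the inputs a lead-time-bias
analysis needs — averaged age-specific cancer incidence rates over 5-year
registry bands for two calendar periods, per-stratum screening proportion
and rate tables, and enrollment age-structure weights — without claiming
any real trial's values. The incidence truth is an exponential-of-cubic
("log-cubic") curve through anchor points shaped like adult lung-cancer
incidence (steep rise from midlife, plateau past 85); the screening tables
encode a configurable between-stratum differential in screening uptake
during the study, emulating a protocol-driven gap such as a mid-trial
change that reduced screening in one stratum only.

Everything is reproducible bit-for-bit from the seed, and truth parameters
are returned alongside the tables so recovery tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .incidence import OPEN_BAND_HALF_WIDTH

__all__ = [
    "FixtureConfig",
    "IncidenceTruth",
    "make_incidence_fixture",
    "make_screening_fixture",
    "make_weights",
    "make_fixture_set",
    "PRESETS",
]

PRESETS = ("null", "biased", "intervention-like")

# log-rate cubic anchor points (age, rate per 100k): near-zero in youth,
# steep rise through midlife, plateau at the oldest ages.
_ANCHORS = ((15.0, 0.5), (45.0, 30.0), (67.5, 300.0), (85.0, 430.0))


@dataclass(frozen=True)
class IncidenceTruth:
    """Coefficients of the true log-rate cubic, lowest order first."""

    coef: tuple[float, float, float, float]
    during_scale: float

    def rate_per_100k(self, age, period: str = "before"):
        age = np.asarray(age, dtype=float)
        c = self.coef
        log_rate = c[0] + c[1] * age + c[2] * age**2 + c[3] * age**3
        scale = self.during_scale if period == "during" else 1.0
        out = scale * np.exp(log_rate)
        return out if out.ndim else float(out)


def _solve_truth(during_scale: float) -> IncidenceTruth:
    ages = np.array([a for a, _ in _ANCHORS])
    log_rates = np.log([r for _, r in _ANCHORS])
    vand = np.vander(ages, 4, increasing=True)
    coef = np.linalg.solve(vand, log_rates)
    return IncidenceTruth(coef=tuple(float(c) for c in coef), during_scale=during_scale)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic inputs.

    ``differential`` in [0, 1] interpolates the exposed stratum's
    during-study screening between the reference level (0, a null study)
    and a saturated protocol-like level (1). ``noise_sd`` is the standard
    deviation of multiplicative lognormal noise on the incidence rates
    (0 = exact truth).
    """

    seed: int = 1
    differential: float = 0.5
    noise_sd: float = 0.0
    during_scale: float = 0.9
    exposed: str = "smoker"
    reference: str = "nonsmoker"
    weights_mode: str = "uniform"  # uniform | trial-like | stratum-specific
    band_width: float = 5.0
    max_band_lo: float = 85.0
    # screening age bins and levels
    screen_edges: tuple[float, ...] = (40.0, 55.0, 65.0, 80.0)
    k1_before: tuple[float, ...] = (0.20, 0.25, 0.30)
    k2_before: tuple[float, ...] = (0.33, 0.33, 0.33)
    k1_during_ref: tuple[float, ...] = (0.30, 0.35, 0.40)
    k2_during_ref: tuple[float, ...] = (0.50, 0.50, 0.50)
    k1_during_high: tuple[float, ...] = (0.85, 0.90, 0.90)
    k2_during_high: tuple[float, ...] = (1.00, 1.00, 1.00)
    age_strata: tuple[tuple[str, float, float], ...] = (
        ("55-59", 55.0, 60.0),
        ("60-64", 60.0, 65.0),
        ("65-69", 65.0, 70.0),
        ("70-74", 70.0, 75.0),
    )
    screenage: float = 40.0
    maxage: float = 100.0


def make_incidence_fixture(config: FixtureConfig) -> tuple[pd.DataFrame, IncidenceTruth]:
    """Registry-style table of 5-year band rates for both periods.

    Bands run 0-5, 5-10, ..., with a final open-ended ``85+`` band (encoded
    as [85, 120) so its midpoint convention, lo + 2.5, applies). Rates are
    evaluated from the truth curve at band midpoints, with optional
    multiplicative noise.
    """
    truth = _solve_truth(config.during_scale)
    rng = np.random.default_rng([config.seed, 101])
    lows = np.arange(0.0, config.max_band_lo + 0.1, config.band_width)
    rows = []
    for period in ("before", "during"):
        for lo in lows:
            open_ended = lo >= config.max_band_lo
            hi = 120.0 if open_ended else lo + config.band_width
            mid = lo + OPEN_BAND_HALF_WIDTH if open_ended else lo + config.band_width / 2
            rate = truth.rate_per_100k(mid, period)
            if config.noise_sd > 0:
                rate *= float(np.exp(rng.normal(0.0, config.noise_sd)))
            rows.append({
                "age_lo": lo, "age_hi": hi,
                "rate_per_100k": rate, "period": period,
            })
    return pd.DataFrame(rows), truth


def make_screening_fixture(config: FixtureConfig) -> pd.DataFrame:
    """Per (stratum, period, age bin) table of k1 and k2.

    Before the study both strata share the same modest background level;
    during the study the exposed stratum's uptake is lifted toward the
    protocol-like high level by ``differential``.
    """
    d = float(np.clip(config.differential, 0.0, 1.0))
    edges = config.screen_edges

    def blend(base, high):
        return tuple((1 - d) * b + d * h for b, h in zip(base, high))

    levels = {
        (config.exposed, "before"): (config.k1_before, config.k2_before),
        (config.reference, "before"): (config.k1_before, config.k2_before),
        (config.exposed, "during"): (
            blend(config.k1_during_ref, config.k1_during_high),
            blend(config.k2_during_ref, config.k2_during_high),
        ),
        (config.reference, "during"): (config.k1_during_ref, config.k2_during_ref),
    }
    rows = []
    for (stratum, period), (k1, k2) in levels.items():
        for j in range(len(edges) - 1):
            rows.append({
                "stratum": stratum, "period": period,
                "age_lo": edges[j], "age_hi": edges[j + 1],
                "k1": k1[j], "k2": k2[j],
            })
    return pd.DataFrame(rows)


_TRIAL_PROFILE = (0.35, 0.30, 0.20, 0.15)
_TRIAL_EXPOSED = (0.30, 0.30, 0.22, 0.18)


def make_weights(config: FixtureConfig) -> pd.DataFrame:
    """Age-stratum weights; each stratum's vector sums to 1.

    ``uniform`` gives equal weights shared by both risk strata;
    ``trial-like`` a front-loaded enrollment age profile (younger bands
    larger, as in a screening-trial cohort); ``stratum-specific`` gives the
    exposed stratum its own, slightly older, profile.
    """
    labels = [s[0] for s in config.age_strata]
    k = len(labels)
    if config.weights_mode == "uniform":
        table = {"all": tuple([1.0 / k] * k)}
    elif config.weights_mode == "trial-like":
        table = {"all": _TRIAL_PROFILE[:k]}
    elif config.weights_mode == "stratum-specific":
        table = {
            config.exposed: _TRIAL_EXPOSED[:k],
            config.reference: _TRIAL_PROFILE[:k],
        }
    else:
        raise ValueError(f"unknown weights_mode {config.weights_mode!r}")
    rows = []
    for stratum, weights in table.items():
        for label, w in zip(labels, weights):
            rows.append({"stratum": stratum, "age_stratum": label, "weight": w})
    return pd.DataFrame(rows)


def preset_config(preset: str, seed: int = 1) -> FixtureConfig:
    """The named study conditions: no gap, a moderate gap, or a protocol gap."""
    if preset == "null":
        return FixtureConfig(seed=seed, differential=0.0)
    if preset == "biased":
        return FixtureConfig(seed=seed, differential=0.5)
    if preset == "intervention-like":
        return FixtureConfig(seed=seed, differential=1.0)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_fixture_set(config: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Write incidence.csv, screening.csv, weights.csv and a scenario.yaml."""
    from . import io as ltbca_io  # local import to avoid a cycle
    from .scenario import default_scenario_dict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    incidence, _ = make_incidence_fixture(config)
    screening = make_screening_fixture(config)
    weights = make_weights(config)
    paths = {
        "incidence": outdir / "incidence.csv",
        "screening": outdir / "screening.csv",
        "weights": outdir / "weights.csv",
        "scenario": outdir / "scenario.yaml",
    }
    ltbca_io.write_incidence_csv(incidence, paths["incidence"])
    ltbca_io.write_screening_csv(screening, paths["screening"])
    ltbca_io.write_weights_csv(weights, paths["weights"])
    ltbca_io.write_scenario_yaml(default_scenario_dict(config), paths["scenario"])
    return paths
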