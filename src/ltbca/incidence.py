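"""Age-specific incidence curves and the back-shift to preclinical onset.

Registry data arrive as averaged rates per 100,000 person-years over 5-year
age bands, split into a *before*-study and a *during*-study calendar period.
A smooth, strictly positive intensity is fitted through the band midpoints
(least squares on the log-rate scale by default) and then shifted backward
in age by the mean preclinical sojourn: the clinical incidence observed at
age ``x + mean`` becomes the preclinical-onset intensity ``w(x)`` at age
``x``, because on average an incident case entered the detectable
preclinical state one mean sojourn earlier.

All curve evaluations return intensities per person-year (the per-100,000
registry scale is divided out exactly once, at fit time).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

PER_100K = 1e5

VALID_PERIODS = ("before", "during")
VALID_FAMILIES = ("logcubic", "logquad", "spline")


class IncidenceFitError(ValueError):
    """Raised when the incidence points cannot support a fit."""


@dataclass(frozen=True)
class IncidencePoint:
    """One registry band: rate per 100,000 person-years over [age_lo, age_hi)."""

    age_lo: float
    age_hi: float
    rate: float
    period: str

    def __post_init__(self):
        if not self.age_lo < self.age_hi:
            raise IncidenceFitError(f"empty age band [{self.age_lo}, {self.age_hi})")
        if self.rate < 0:
            raise IncidenceFitError(f"negative rate {self.rate}")
        if self.period not in VALID_PERIODS:
            raise IncidenceFitError(f"period must be one of {VALID_PERIODS}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)


# Half-width attached to the final open-ended band (e.g. "85+"), consistent
# with 5-year registry bands.
OPEN_BAND_HALF_WIDTH = 2.5


def band_midpoints(points: list[IncidencePoint], open_ended_last: bool = True) -> np.ndarray:
    """Midpoints of the bands; the last band may be open-ended (lo + 2.5y)."""
    mids = np.array([p.midpoint for p in points], dtype=float)
    if open_ended_last and len(points) > 0:
        mids[-1] = points[-1].age_lo + OPEN_BAND_HALF_WIDTH
    return mids


@dataclass(frozen=True)
class IncidenceCurve:
    """Continuous nonnegative intensity over age ``[0, maxage]``.

    ``shift`` > 0 means the curve has been moved backward in age:
    evaluation at ``x`` reads the fitted clinical curve at ``x + shift``
    (clamped at ``maxage``).
    """

    period: str
    family: str
    model: object  # numpy Polynomial (log-rate scale) or PchipInterpolator
    maxage: float
    shift: float = 0.0
    rss: float = 0.0  # residual sum of squares on the fitting scale

    def _log_rate(self, age: np.ndarray) -> np.ndarray:
        if self.family in ("logcubic", "logquad"):
            return self.model(age)
        return self.model(np.clip(age, self.model.x[0], self.model.x[-1]))

    def __call__(self, age):
        """Preclinical-onset intensity per person-year at ``age``."""
        age = np.asarray(age, dtype=float)
        eff = np.clip(age + self.shift, 0.0, self.maxage)
        out = np.exp(self._log_rate(eff)) / PER_100K
        return out if out.ndim else float(out)

    def rate_per_100k(self, age):
        """Intensity on the registry scale (cases per 100,000 person-years)."""
        val = np.asarray(self(age)) * PER_100K
        return val if val.ndim else float(val)


def fit_incidence_curve(
    points: list[IncidencePoint],
    period: str,
    family: str = "logcubic",
    scale: str = "log",
    maxage: float = 100.0,
) -> IncidenceCurve:
    """Fit a smooth positive intensity through the band midpoints.

    Parameters
    ----------
    points
        Registry bands; only those matching ``period`` are used.
    family
        ``logcubic`` (default): exponential of a cubic polynomial in age,
        guaranteeing positivity and matching the convex rise / late plateau
        of adult cancer incidence. ``logquad``: quadratic variant.
        ``spline``: monotone cubic (PCHIP) interpolant of the log rates.
    scale
        ``log`` fits least squares on log rates (default); ``rate`` fits on
        the raw rate scale by nonlinear least squares with the log-scale fit
        as the starting point.
    """
    if period not in VALID_PERIODS:
        raise IncidenceFitError(f"period must be one of {VALID_PERIODS}")
    if family not in VALID_FAMILIES:
        raise IncidenceFitError(f"unknown family {family!r}")
    if scale not in ("log", "rate"):
        raise IncidenceFitError(f"scale must be 'log' or 'rate', got {scale!r}")

    sel = [p for p in points if p.period == period]
    sel.sort(key=lambda p: p.age_lo)
    usable = [p for p in sel if p.rate > 0]
    if len(sel) > 0 and len(usable) == 0:
        raise IncidenceFitError(f"all rates are zero for period {period!r}")
    deg = {"logcubic": 3, "logquad": 2}.get(family, 3)
    if len(usable) < max(4, deg + 1):
        raise IncidenceFitError(
            f"need at least {max(4, deg + 1)} positive-rate points for period "
            f"{period!r}, got {len(usable)}"
        )

    mids = band_midpoints(usable)
    rates = np.array([p.rate for p in usable], dtype=float)
    log_rates = np.log(rates)

    if family == "spline":
        model = PchipInterpolator(mids, log_rates)
        rss = 0.0
        return IncidenceCurve(period=period, family=family, model=model,
                              maxage=maxage, rss=rss)

    poly = np.polynomial.Polynomial.fit(mids, log_rates, deg=deg)
    if scale == "rate":
        coef0 = poly.coef.copy()

        def resid(c):
            p = poly.copy()
            # replace scaled-domain coefficients, keep the domain mapping
            p.coef = c
            return np.exp(p(mids)) - rates

        sol = least_squares(resid, coef0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise IncidenceFitError(
                f"rate-scale optimizer did not converge for period {period!r}: "
                f"{sol.message}"
            )
        poly.coef = sol.x
        rss = float(np.sum(sol.fun**2))
    else:
        rss = float(np.sum((poly(mids) - log_rates) ** 2))

    return IncidenceCurve(period=period, family=family, model=poly,
                          maxage=maxage, rss=rss)


def shift_to_preclinical(curve: IncidenceCurve, mean_duration: float) -> IncidenceCurve:
    """Back-shift a clinical incidence curve by the mean sojourn.

    The returned curve evaluates ``w(x) = curve(x + mean_duration)``; ages
    beyond ``maxage - mean_duration`` are clamped to the curve's value at
    ``maxage``.
    """
    if mean_duration < 0:
        raise IncidenceFitError(f"mean_duration must be >= 0, got {mean_duration}")
    return replace(curve, shift=curve.shift + float(mean_duration))
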