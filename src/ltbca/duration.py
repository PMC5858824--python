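"""Preclinical sojourn-time (duration) distributions.

The time an individual spends in the detectable preclinical state — from
preclinical onset at age ``x`` to symptomatic diagnosis at age ``z`` — is
modelled as a lognormal random variable ``t = z - x``, parameterized by its
*mode* and *standard deviation* in years rather than by the underlying
location/scale pair, because mode and sd are the quantities with a direct
clinical reading (typical sojourn, spread of sojourns).

Overdiagnosis is represented as a mixture: a minority component with a very
long mode stands in for disease that would never surface clinically within
the modelled horizon, so that screen detection of such individuals inflates
observed incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LognormalDurationSpec",
    "MixtureDurationSpec",
    "lognormal_from_mode_sd",
    "overdiagnosis_mixture",
    "duration_density",
    "duration_cdf",
    "duration_survival",
    "duration_mean",
]


class DurationParameterError(ValueError):
    """Raised for out-of-domain mode/sd parameters."""


class DurationSolveError(RuntimeError):
    """Raised when the mode/sd -> (mu, sigma) solve does not converge."""


@dataclass(frozen=True)
class LognormalDurationSpec:
    """A lognormal sojourn distribution pinned down by its mode and sd.

    ``mu`` and ``sigma`` are the location and scale of the underlying
    normal, i.e. ``log t ~ Normal(mu, sigma^2)``; they are derived from
    (mode, sd) at construction time (see :func:`lognormal_from_mode_sd`).
    """

    mode: float
    sd: float
    mu: float
    sigma: float

    @property
    def _frozen(self) -> stats.rv_continuous:
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t > 0, self._frozen.pdf(np.maximum(t, 1e-300)), 0.0)
        return out if out.ndim else float(out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t > 0, self._frozen.cdf(np.maximum(t, 1e-300)), 0.0)
        return out if out.ndim else float(out)

    def sf(self, t):
        return 1.0 - self.cdf(t)

    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    def implied_mode(self) -> float:
        """Mode recomputed from (mu, sigma); round-trips the input mode."""
        return float(np.exp(self.mu - self.sigma**2))

    def implied_sd(self) -> float:
        s2 = self.sigma**2
        var = (np.exp(s2) - 1.0) * np.exp(2.0 * self.mu + s2)
        return float(np.sqrt(var))

    def rvs(self, size, random_state):
        return self._frozen.rvs(size=size, random_state=random_state)


@dataclass(frozen=True)
class MixtureDurationSpec:
    """Weighted mixture of lognormal sojourn components.

    Used for the overdiagnosis scenario: a fraction of the population draws
    its sojourn from a long-mode component and, if screen-detected, would
    never have surfaced clinically within the study horizon.
    By convention the *last* component is the overdiagnosis (long) one.
    """

    components: tuple[LognormalDurationSpec, ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if len(self.components) != len(self.weights):
            raise DurationParameterError("components and weights differ in length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise DurationParameterError(
                f"mixture weights must be nonnegative and sum to 1, got {self.weights}"
            )

    def pdf(self, t):
        return sum(w * c.pdf(t) for c, w in zip(self.components, self.weights))

    def cdf(self, t):
        return sum(w * c.cdf(t) for c, w in zip(self.components, self.weights))

    def sf(self, t):
        return 1.0 - self.cdf(t)

    def mean(self) -> float:
        return float(sum(w * c.mean() for c, w in zip(self.components, self.weights)))


DurationSpec = LognormalDurationSpec | MixtureDurationSpec


def lognormal_from_mode_sd(mode: float, sd: float) -> LognormalDurationSpec:
    """Solve for the lognormal with the requested mode and sd (years).

    Substituting the mode constraint ``mu = log(mode) + sigma^2`` into the
    variance identity leaves one monotone equation in ``v = sigma^2``::

        (exp(v) - 1) * mode^2 * exp(3 v) = sd^2

    which is solved by bracketed root-finding to 1e-10.
    """
    if not (mode > 0) or not (sd > 0):
        raise DurationParameterError(f"mode and sd must be > 0, got mode={mode}, sd={sd}")

    target = sd * sd
    m2 = mode * mode

    def g(v):
        return np.expm1(v) * m2 * np.exp(3.0 * v) - target

    lo, hi = 1e-15, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for finite sd
            raise DurationSolveError(
                f"could not bracket sigma^2 for mode={mode}, sd={sd}"
            )
    try:
        v = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=1e-14, maxiter=500)
    except Exception as exc:  # pragma: no cover - brentq is robust once bracketed
        raise DurationSolveError(
            f"root-finding failed for mode={mode}, sd={sd}: {exc}"
        ) from exc
    sigma = float(np.sqrt(v))
    mu = float(np.log(mode) + v)
    spec = LognormalDurationSpec(mode=float(mode), sd=float(sd), mu=mu, sigma=sigma)
    if abs(spec.implied_mode() - mode) > 1e-6 * mode or abs(spec.implied_sd() - sd) > 1e-6 * sd:
        raise DurationSolveError(
            f"mode/sd round-trip failed for mode={mode}, sd={sd}"
        )
    return spec


def overdiagnosis_mixture(
    base: LognormalDurationSpec,
    weight: float = 0.2,
    long_mode: float = 20.0,
    long_sd: float = 3.0,
) -> MixtureDurationSpec:
    """Mixture placing ``weight`` of the population on a long-sojourn component."""
    if not (0.0 < weight < 1.0):
        raise DurationParameterError(f"overdiagnosis weight must be in (0,1), got {weight}")
    long_comp = lognormal_from_mode_sd(long_mode, long_sd)
    return MixtureDurationSpec(
        components=(base, long_comp), weights=(1.0 - weight, weight)
    )


def duration_density(spec: DurationSpec, t):
    """Density of the sojourn time at ``t`` years; 0 for ``t <= 0``."""
    return spec.pdf(t)


def duration_cdf(spec: DurationSpec, t):
    """P(sojourn <= t); 0 for ``t <= 0``."""
    return spec.cdf(t)


def duration_survival(spec: DurationSpec, t):
    """P(sojourn > t)."""
    return spec.sf(t)


def duration_mean(spec: DurationSpec) -> float:
    """Mean sojourn in years (closed form; weighted for mixtures)."""
    return spec.mean()
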