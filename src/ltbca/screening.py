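"""Screening behavior (who screens, how often) and screen-detection.

Screening use is summarized per risk-factor stratum and calendar period
("before" vs "during" the study) by two age-specific step functions:

* ``k1(age)`` — proportion of the stratum that ever screens, in [0, 1];
* ``k2(age)`` — screens per year among those who screen, >= 0.

Both are step functions over half-open age bins, extended outside the
observed bins by nearest-bin constants. Detection of preclinical disease is
governed by a per-screen sensitivity ``xi``: over an age interval the
expected number of screens is ``N = \\int k2`` and, under the default
*geometric* form, a screener escapes detection with probability
``(1 - xi)^N`` — independent screens at fixed sensitivity. A literal
*linear* form, ``detect = k1 * min(1, xi * N)``, is retained as a clamped
configuration option for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningBehavior",
    "ScreeningPolicy",
    "expected_screens",
    "detection_probability",
    "behavior_from_survey",
    "SurveyBin",
]


class ScreeningDataError(ValueError):
    """Raised for inconsistent screening bins or survey counts."""


class IntervalError(ValueError):
    """Raised when an age interval has u > v."""


@dataclass(frozen=True)
class ScreeningBehavior:
    """Step functions ``k1`` (proportion) and ``k2`` (screens/yr) over age bins.

    ``edges`` has length ``nbins + 1``; bin ``j`` covers ``[edges[j], edges[j+1])``.
    Outside the covered range the nearest bin's values extend as constants.
    """

    stratum: str
    period: str
    edges: tuple[float, ...]
    k1: tuple[float, ...]
    k2: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        p1 = np.asarray(self.k1, dtype=float)
        p2 = np.asarray(self.k2, dtype=float)
        if len(e) < 2 or len(p1) != len(e) - 1 or len(p2) != len(e) - 1:
            raise ScreeningDataError(
                f"need nbins+1 edges for nbins k1/k2 values "
                f"(got {len(e)} edges, {len(p1)} k1, {len(p2)} k2)"
            )
        if np.any(np.diff(e) <= 0):
            raise ScreeningDataError("age-bin edges must be strictly increasing")
        if np.any(p1 < 0) or np.any(p1 > 1):
            raise ScreeningDataError("k1 must lie in [0, 1]")
        if np.any(p2 < 0):
            raise ScreeningDataError("k2 must be >= 0")

    def _bin_index(self, age: np.ndarray) -> np.ndarray:
        e = np.asarray(self.edges)
        idx = np.searchsorted(e, age, side="right") - 1
        return np.clip(idx, 0, len(e) - 2)

    def k1_at(self, age):
        """Proportion ever screened at ``age`` (nearest-bin outside range)."""
        age = np.asarray(age, dtype=float)
        out = np.asarray(self.k1, dtype=float)[self._bin_index(age)]
        return out if out.ndim else float(out)

    def k2_at(self, age):
        """Screens per year among screeners at ``age``."""
        age = np.asarray(age, dtype=float)
        out = np.asarray(self.k2, dtype=float)[self._bin_index(age)]
        return out if out.ndim else float(out)

    def cumulative_screens(self, age):
        """``K2(age) = \\int_{edges[0]}^{age} k2(y) dy`` (signed, pw-linear).

        Extends linearly with the first/last bin rate outside the bins, per
        the nearest-bin-constant extrapolation of ``k2``.
        """
        e = np.asarray(self.edges, dtype=float)
        r = np.asarray(self.k2, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(e) * r)])
        age = np.asarray(age, dtype=float)
        out = np.interp(age, e, cum)
        below = age < e[0]
        above = age > e[-1]
        out = np.where(below, (age - e[0]) * r[0], out)
        out = np.where(above, cum[-1] + (age - e[-1]) * r[-1], out)
        return out if out.ndim else float(out)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(self.edges)


@dataclass(frozen=True)
class ScreeningPolicy:
    """Test sensitivity, recommended starting age, and detection form."""

    sensitivity: float
    screenage: float
    detection_form: str = "geometric"
    linear_sensitivity: float | None = None  # xi' of the linear form; None -> xi

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ScreeningDataError(
                f"sensitivity must be in [0, 1], got {self.sensitivity}"
            )
        if self.screenage < 0:
            raise ScreeningDataError(f"screenage must be >= 0, got {self.screenage}")
        if self.detection_form not in ("geometric", "linear"):
            raise ScreeningDataError(
                f"detection_form must be 'geometric' or 'linear', got {self.detection_form!r}"
            )


def expected_screens(behavior: ScreeningBehavior, u, v):
    """Expected number of screens ``N = \\int_u^v k2(y) dy`` for a screener.

    Exact for step functions (sum of bin-width x rate overlaps). ``u`` and
    ``v`` may be arrays (broadcast); requires ``u <= v`` elementwise.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u > v):
        raise IntervalError("expected_screens requires u <= v")
    out = behavior.cumulative_screens(v) - behavior.cumulative_screens(u)
    out = np.maximum(out, 0.0)
    return out if np.ndim(out) else float(out)


def escape_probability(policy: ScreeningPolicy, n_screens):
    """P(an existing preclinical case escapes N expected screens | screener)."""
    n = np.asarray(n_screens, dtype=float)
    xi = policy.sensitivity
    if policy.detection_form == "geometric":
        if xi >= 1.0:
            out = np.where(n > 0, 0.0, 1.0)
        else:
            out = np.power(1.0 - xi, n)
    else:
        xi_lin = xi if policy.linear_sensitivity is None else policy.linear_sensitivity
        out = 1.0 - np.minimum(1.0, xi_lin * n)
    return out if out.ndim else float(out)


def detection_probability(
    behavior: ScreeningBehavior,
    policy: ScreeningPolicy,
    onset_age,
    u,
    v,
):
    """P(screen-detected over ages ``[u, v]``) for onset at ``onset_age``.

    Screens can only detect once detectable preclinical disease exists and
    screening has begun, so the effective interval starts at
    ``L = max(onset_age, screenage, u)``. The result is
    ``k1(onset_age) * (1 - escape(N(L, v)))`` and lies in ``[0, k1(onset_age)]``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u > v):
        raise IntervalError("detection_probability requires u <= v")
    x = np.asarray(onset_age, dtype=float)
    lower = np.maximum(np.maximum(x, policy.screenage), u)
    n = expected_screens(behavior, np.minimum(lower, v), v)
    out = behavior.k1_at(x) * (1.0 - escape_probability(policy, n))
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class SurveyBin:
    """Questionnaire counts for one age bin.

    ``n_screened_1`` answered "screened once" and ``n_screened_2plus``
    "twice or more" within the recall window of ``window_years``.
    """

    age_lo: float
    age_hi: float
    n_total: int
    n_screened_1: int
    n_screened_2plus: int
    window_years: float


def behavior_from_survey(
    bins: list[SurveyBin],
    stratum: str,
    period: str,
    two_plus_value: float = 2.0,
) -> ScreeningBehavior:
    """Convert ever-screened / times-screened questionnaire counts to (k1, k2).

    Per bin: ``k1 = n_ever / n_total`` and
    ``k2 = (n_once + two_plus_value * n_2plus) / (n_ever * window_years)``,
    the per-year screening rate among screeners over the recall window. The
    open "2+" category contributes ``two_plus_value`` screens (default 2, a
    conservative floor). Bins with ``n_total == 0`` are dropped with a
    warning; ``n_ever == 0`` gives ``k1 = k2 = 0``.
    """
    bins = sorted(bins, key=lambda b: b.age_lo)
    edges: list[float] = []
    k1: list[float] = []
    k2: list[float] = []
    for b in bins:
        n_ever = b.n_screened_1 + b.n_screened_2plus
        if min(b.n_total, b.n_screened_1, b.n_screened_2plus) < 0:
            raise ScreeningDataError(f"negative survey counts in bin [{b.age_lo}, {b.age_hi})")
        if n_ever > b.n_total:
            raise ScreeningDataError(
                f"bin [{b.age_lo}, {b.age_hi}): {n_ever} ever-screened exceeds "
                f"{b.n_total} respondents"
            )
        if b.window_years <= 0:
            raise ScreeningDataError("window_years must be > 0")
        if b.n_total == 0:
            logger.warning(
                "dropping empty survey bin [%s, %s) for stratum=%s period=%s",
                b.age_lo, b.age_hi, stratum, period,
            )
            continue
        if edges and abs(b.age_lo - edges[-1]) > 1e-12:
            raise ScreeningDataError("survey bins must be contiguous after dropping empties")
        if not edges:
            edges.append(b.age_lo)
        edges.append(b.age_hi)
        k1.append(n_ever / b.n_total)
        if n_ever == 0:
            k2.append(0.0)
        else:
            total_screens = b.n_screened_1 + two_plus_value * b.n_screened_2plus
            k2.append(total_screens / (n_ever * b.window_years))
    if not k1:
        raise ScreeningDataError("no usable survey bins")
    return ScreeningBehavior(
        stratum=stratum, period=period,
        edges=tuple(edges), k1=tuple(k1), k2=tuple(k2),
    )
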