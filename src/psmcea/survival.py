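"""Parametric survival curves used for extrapolating OS and PFS.

All curves live on a weekly time axis (the partitioned-survival engine uses
1-week cycles), so every rate parameter is per week and every location
parameter is in log-weeks.  Seven families are supported -- the ones
routinely fitted when extrapolating digitized trial Kaplan-Meier curves:

======================  ==========================  =========================
family                  parameters (ordered)        survival function S(t)
======================  ==========================  =========================
exponential             rate                        exp(-rate*t)
weibull                 shape, rate                 exp(-(rate*t)^shape)
gamma                   shape, rate                 1 - P(shape, rate*t)
lognormal               mu, sigma                   1 - Phi((ln t - mu)/sigma)
gompertz                shape, rate                 exp(-rate/shape*(e^(shape*t)-1))
loglogistic             shape, rate                 1 / (1 + (rate*t)^shape)
generalized_gamma       mu, sigma, Q                Prentice (mu, sigma, Q) form
======================  ==========================  =========================

The log-logistic is parameterized with a *rate* (``S(t) = 1/(1+(rate*t)^shape)``,
median = 1/rate) rather than a scale; with this convention the published
shape/rate pairs for the serplulimab arm reproduce the reported restricted
areas, which is how the convention was pinned down.  The Gompertz shape may
be negative (and degenerates to the exponential as shape -> 0); the
generalized gamma uses the (mu, sigma, Q) form and degenerates to the
lognormal at Q = 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

__all__ = [
    "Family",
    "ParametricSurvival",
    "ProportionalHazards",
    "WEEKS_PER_YEAR",
    "discount_factors",
]

#: Year length used when converting weekly areas to (life-)years and when
#: discounting.  52 weeks/year keeps the 10-year horizon at exactly 520
#: one-week cycles.
WEEKS_PER_YEAR = 52.0


class Family(str, enum.Enum):
    """Supported parametric families, in canonical (tie-break) order."""

    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    GOMPERTZ = "gompertz"
    LOGLOGISTIC = "loglogistic"
    GENERALIZED_GAMMA = "generalized_gamma"

    @property
    def n_params(self) -> int:
        return {"exponential": 1, "weibull": 2, "gamma": 2, "lognormal": 2,
                "gompertz": 2, "loglogistic": 2,
                "generalized_gamma": 3}[self.value]

    @property
    def param_names(self) -> tuple[str, ...]:
        return {
            "exponential": ("rate",),
            "weibull": ("shape", "rate"),
            "gamma": ("shape", "rate"),
            "lognormal": ("mu", "sigma"),
            "gompertz": ("shape", "rate"),
            "loglogistic": ("shape", "rate"),
            "generalized_gamma": ("mu", "sigma", "Q"),
        }[self.value]


class ParameterDomainError(ValueError):
    """Raised for non-finite or inadmissible survival parameters."""


def _validate(family: Family, params: np.ndarray) -> None:
    if not np.all(np.isfinite(params)):
        raise ParameterDomainError(f"{family.value}: non-finite parameters {params}")
    if len(params) != family.n_params:
        raise ParameterDomainError(
            f"{family.value} takes {family.n_params} parameters, got {len(params)}")
    names = family.param_names
    for name, value in zip(names, params):
        # sigma, rates and non-Gompertz shapes must be strictly positive;
        # mu, Q and the Gompertz shape are unrestricted reals.
        positive = name in ("rate", "sigma") or (
            name == "shape" and family is not Family.GOMPERTZ)
        if positive and value <= 0:
            # degenerate rate-0 exponential (S == 1) is allowed as an
            # explicit edge case for static-cohort checks
            if family is Family.EXPONENTIAL and value == 0:
                continue
            raise ParameterDomainError(
                f"{family.value}: parameter {name}={value} must be > 0")


def _gengamma_logsf(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    """log S(t) for the Prentice generalized gamma; lognormal at q == 0."""
    w = (np.log(t) - mu) / sigma
    if abs(q) < 1e-9:
        return stats.norm.logsf(w)
    a = q ** -2
    u = a * np.exp(q * w)
    if q > 0:
        return np.log1p(-special.gammainc(a, u))
    return np.log(special.gammainc(a, u))


def _gengamma_logpdf(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    w = (np.log(t) - mu) / sigma
    if abs(q) < 1e-9:
        return stats.norm.logpdf(w) - np.log(sigma * t)
    a = q ** -2
    return (np.log(abs(q)) + a * np.log(a) - special.gammaln(a)
            + a * (q * w - np.exp(q * w)) - np.log(sigma * t))


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival curve (family + parameter vector), time in weeks.

    Instances are immutable and answer ``survival(t)``, ``hazard(t)``,
    ``median()`` and restricted (optionally discounted) areas.

    Examples
    --------
    >>> m = ParametricSurvival("loglogistic", (1.7870, 0.0124))
    >>> round(m.median(), 2)
    80.65
    """

    family: Family
    params: tuple[float, ...]

    def __init__(self, family: Family | str, params: Sequence[float]):
        fam = Family(family)
        arr = np.asarray(params, dtype=float)
        _validate(fam, arr)
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "params", tuple(arr))

    # -- core functions -----------------------------------------------------

    def logsf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        p = self.params
        out = np.zeros_like(t, dtype=float)
        pos = t > 0
        tp = t[pos]
        fam = self.family
        if fam is Family.EXPONENTIAL:
            out[pos] = -p[0] * tp
        elif fam is Family.WEIBULL:
            out[pos] = -((p[1] * tp) ** p[0])
        elif fam is Family.GAMMA:
            out[pos] = stats.gamma.logsf(tp, p[0], scale=1.0 / p[1])
        elif fam is Family.LOGNORMAL:
            out[pos] = stats.norm.logsf((np.log(tp) - p[0]) / p[1])
        elif fam is Family.GOMPERTZ:
            a, b = p
            if abs(a) < 1e-12:
                out[pos] = -b * tp
            else:
                out[pos] = -b / a * np.expm1(a * tp)
        elif fam is Family.LOGLOGISTIC:
            out[pos] = -np.log1p((p[1] * tp) ** p[0])
        else:
            out[pos] = _gengamma_logsf(tp, *p)
        return out

    def survival(self, t) -> np.ndarray:
        """S(t): probability of surviving beyond ``t`` weeks; S(0) = 1."""
        return np.exp(self.logsf(t))

    def logpdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        fam = self.family
        with np.errstate(divide="ignore"):
            if fam is Family.EXPONENTIAL:
                return math.log(p[0]) - p[0] * t
            if fam is Family.WEIBULL:
                return stats.weibull_min.logpdf(t, p[0], scale=1.0 / p[1])
            if fam is Family.GAMMA:
                return stats.gamma.logpdf(t, p[0], scale=1.0 / p[1])
            if fam is Family.LOGNORMAL:
                return stats.lognorm.logpdf(t, p[1], scale=math.exp(p[0]))
            if fam is Family.GOMPERTZ:
                a, b = p
                if abs(a) < 1e-12:
                    return math.log(b) - b * t
                return np.log(b) + a * t - b / a * np.expm1(a * t)
            if fam is Family.LOGLOGISTIC:
                return stats.fisk.logpdf(t, p[0], scale=1.0 / p[1])
            return _gengamma_logpdf(t, *p)

    def hazard(self, t) -> np.ndarray:
        """h(t) = f(t) / S(t)."""
        return np.exp(self.logpdf(t) - self.logsf(t))

    # -- summaries ----------------------------------------------------------

    def median(self) -> float:
        """Time t (weeks) with S(t) = 1/2; closed form where one exists."""
        p = self.params
        fam = self.family
        ln2 = math.log(2.0)
        if fam is Family.EXPONENTIAL:
            return ln2 / p[0]
        if fam is Family.WEIBULL:
            return ln2 ** (1.0 / p[0]) / p[1]
        if fam is Family.LOGNORMAL:
            return math.exp(p[0])
        if fam is Family.LOGLOGISTIC:
            return 1.0 / p[1]
        if fam is Family.GOMPERTZ:
            a, b = p
            if abs(a) < 1e-12:
                return ln2 / b
            arg = 1.0 + a * ln2 / b
            if arg <= 0:  # defective distribution: S plateaus above 1/2
                raise ValueError("survival never reaches 0.5 (defective Gompertz)")
            return math.log(arg) / a
        return self._median_bisect()

    def _median_bisect(self) -> float:
        f = lambda t: self.survival(t) - 0.5
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("survival never reaches 0.5 on [0, 1e6] weeks")
        return brentq(f, 0.0, hi, xtol=1e-10)

    def quantile(self, p: float) -> float:
        """Inverse survival: t with S(t) = 1 - p (p = cumulative probability)."""
        if not 0.0 <= p < 1.0:
            raise ValueError("p must be in [0, 1)")
        if p == 0.0:
            return 0.0
        f = lambda t: self.survival(t) - (1.0 - p)
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e9:
                return math.inf
        return brentq(f, 0.0, hi, xtol=1e-12 * max(hi, 1.0))

    def inverse_survival(self, u) -> np.ndarray:
        """t such that S(t) = u (vectorized); inf where S never falls to u."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u > 1)):
            raise ValueError("survival level must be in (0, 1]")
        p = self.params
        fam = self.family
        with np.errstate(all="ignore"):
            if fam is Family.EXPONENTIAL:
                if p[0] == 0:
                    return np.where(u < 1.0, np.inf, 0.0)
                return -np.log(u) / p[0]
            if fam is Family.WEIBULL:
                return (-np.log(u)) ** (1.0 / p[0]) / p[1]
            if fam is Family.GAMMA:
                return stats.gamma.isf(u, p[0], scale=1.0 / p[1])
            if fam is Family.LOGNORMAL:
                return np.exp(p[0] + p[1] * stats.norm.isf(u))
            if fam is Family.GOMPERTZ:
                a, b = p
                if abs(a) < 1e-12:
                    return -np.log(u) / b
                arg = 1.0 - a * np.log(u) / b
                return np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a,
                                np.inf)
            if fam is Family.LOGLOGISTIC:
                return ((1.0 - u) / u) ** (1.0 / p[0]) / p[1]
        # generalized gamma: no closed form; bisect per point
        return np.array([self.quantile(1.0 - ui) for ui in np.atleast_1d(u)])

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times by inverse-CDF sampling."""
        return self.inverse_survival(rng.uniform(size=n))

    def restricted_area(self, horizon_weeks: float, annual_discount: float = 0.0,
                        cycle_weeks: float = 1.0,
                        discount_mode: str = "annual") -> float:
        """Discounted restricted area under S, in years.

        Trapezoid rule on the same weekly cycle grid the partitioned-survival
        engine uses, with per-interval discount factors evaluated at interval
        midpoints (see :func:`discount_factors`).
        """
        if horizon_weeks <= 0:
            raise ValueError("horizon must be positive")
        if not 0.0 <= annual_discount < 1.0:
            raise ValueError("annual_discount must be in [0, 1)")
        grid = np.arange(0.0, horizon_weeks + 0.5 * cycle_weeks, cycle_weeks)
        s = self.survival(grid)
        seg = 0.5 * (s[:-1] + s[1:]) * np.diff(grid)
        df = discount_factors(0.5 * (grid[:-1] + grid[1:]), annual_discount,
                              discount_mode)
        return float(np.sum(seg * df) / WEEKS_PER_YEAR)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{n}={v:g}" for n, v in
                          zip(self.family.param_names, self.params))
        return f"ParametricSurvival({self.family.value}: {pairs})"


@dataclass(frozen=True)
class ProportionalHazards:
    """A survival curve derived from another by a hazard ratio.

    Under proportional hazards ``S(t) = S_ref(t)**hr``.  With ``hr > 1`` the
    derived curve is worse than the reference.  Used to build the
    chemotherapy-arm curves from the fitted treatment-arm curves (hr = 1/HR
    of treatment vs chemotherapy) and to vary hazard ratios in sensitivity
    and subgroup analyses.
    """

    base: "ParametricSurvival | ProportionalHazards"
    hr: float

    def __post_init__(self):
        if not (np.isfinite(self.hr) and self.hr > 0):
            raise ParameterDomainError(f"hazard ratio must be > 0, got {self.hr}")

    def logsf(self, t) -> np.ndarray:
        return self.hr * self.base.logsf(t)

    def survival(self, t) -> np.ndarray:
        return np.exp(self.logsf(t))

    def hazard(self, t) -> np.ndarray:
        return self.hr * self.base.hazard(t)

    def median(self) -> float:
        f = lambda t: self.survival(t) - 0.5
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e6:
                raise ValueError("survival never reaches 0.5 on [0, 1e6] weeks")
        return brentq(f, 0.0, hi, xtol=1e-10)

    restricted_area = ParametricSurvival.restricted_area

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProportionalHazards({self.base!r}, hr={self.hr:g})"


def discount_factors(times_weeks, annual_rate: float,
                     mode: str = "annual") -> np.ndarray:
    """Discount factors at the given times (weeks) for an annual rate.

    mode="annual"
        Year-bucket factors ``(1+r)^(-floor(t/52))``: everything accruing in
        model year *k* is discounted by the same factor.  This is the literal
        reading of "discounted annually" and is the package default.
    mode="continuous"
        Continuous-equivalent factors ``(1+r)^(-t/52)``.
    """
    t = np.asarray(times_weeks, dtype=float)
    if annual_rate == 0.0:
        return np.ones_like(t)
    years = t / WEEKS_PER_YEAR
    if mode == "annual":
        years = np.floor(years)
    elif mode != "continuous":
        raise ValueError(f"unknown discount mode {mode!r}")
    return (1.0 + annual_rate) ** (-years)
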