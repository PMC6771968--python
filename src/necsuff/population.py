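"""Exact and quadrature-based population values of DN, DS and EV.

Three scenario families cover the standard study designs:

* a dichotomous factor against a dichotomous outcome, parameterised by
  the disease probability P(D), the probability alpha of the harmful
  level, and the odds ratio OR (closed forms on the 2x2 cell
  probabilities);
* a standard-normal factor with a logistic link (per-SD odds ratio and
  target marginal P(D); conditional expectations by adaptive
  quadrature);
* a two-point exponential survival mixture (hazard ratio HR, harmful
  level of probability alpha and hazard 1, protective level hazard
  1/HR), with type I or administrative censoring at a horizon tau.

These are the references the sampling-based estimators are validated
against: a consistent estimator applied to a large sample from one of
these scenarios must approach the population value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize, stats
from scipy.special import expit, logit

from .binary import TwoByTwoTable, measures_from_2x2
from .errors import InfeasibleScenarioError, InvalidBaselineError

__all__ = [
    "TwoByTwoScenario",
    "LogisticNormalScenario",
    "SurvivalScenario",
    "Pop2x2Result",
    "LogisticNormalResult",
    "SurvivalPopResult",
    "cells_from_scenario",
    "pop_measures_2x2",
    "solve_logistic_intercept",
    "pop_measures_logistic_normal",
    "pop_measures_survival",
]

_QUAD_TOL = 1e-8
_NORM_RANGE = 14.0  # +- range covering the standard normal to ~1e-44


# ---------------------------------------------------------------------------
# dichotomous factor, dichotomous outcome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwoScenario:
    """(P(D), alpha, OR) parameterisation of a 2x2 population.

    ``odds_ratio`` may be any value in [0, inf]; 0 and inf are handled
    as exact structural-zero tables rather than numerical limits.  By
    convention alpha is the probability of the *harmful* level, which is
    X=1 when OR > 1 and X=0 when OR < 1.
    """

    p_d: float
    alpha: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_d < 1.0):
            raise InvalidBaselineError(f"p_d={self.p_d!r} must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise InfeasibleScenarioError(f"alpha={self.alpha!r} must be in (0, 1)")
        if math.isnan(self.odds_ratio) or self.odds_ratio < 0.0:
            raise InfeasibleScenarioError("odds_ratio must be in [0, inf]")


def _solve_joint(p_d: float, pi: float, orr: float) -> float:
    """P(D, X=1) given margins (p_d, pi=P(X=1)) and odds ratio >= 1."""
    if orr == 1.0:
        return p_d * pi
    if math.isinf(orr):
        return min(p_d, pi)
    # d (1 - p_d - pi + d) = orr (pi - d)(p_d - d), quadratic in d
    A = 1.0 - orr
    B = (1.0 - p_d - pi) + orr * (pi + p_d)
    C = -orr * pi * p_d
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise InfeasibleScenarioError("no real root for the joint distribution")
    # numerically stable quadratic roots
    q = -0.5 * (B + math.copysign(math.sqrt(disc), B))
    roots = [q / A, C / q]
    hi = min(p_d, pi)
    eps = 1e-12
    for r in roots:
        if -eps <= r <= hi + eps:
            return min(max(r, 0.0), hi)
    raise InfeasibleScenarioError(
        f"no admissible cell probability for p_d={p_d}, alpha={pi}, or={orr}"
    )


def cells_from_scenario(s: TwoByTwoScenario) -> Tuple[float, float, float, float]:
    """Cell probabilities (a, b, c, d) matching the scenario's margins and OR.

    Layout: a = P(X=0, no D), b = P(X=1, no D), c = P(X=0, D),
    d = P(X=1, D).  For OR < 1 the harmful level is X=0, so the solution
    for the reciprocal odds ratio is computed and the columns swapped.
    """
    orr = s.odds_ratio
    if orr >= 1.0 or math.isinf(orr):
        pi = s.alpha  # harmful level X=1
        d = _solve_joint(s.p_d, pi, orr)
        c = s.p_d - d
        b = pi - d
        a = 1.0 - s.p_d - pi + d
        cells = (a, b, c, d)
    else:
        inv = math.inf if orr == 0.0 else 1.0 / orr
        a, b, c, d = cells_from_scenario(
            TwoByTwoScenario(s.p_d, s.alpha, inv)
        )
        cells = (b, a, d, c)  # harmful level X=0: swap exposure coding
    if min(cells) < -1e-12:
        raise InfeasibleScenarioError(f"negative cell probability: {cells}")
    return tuple(max(v, 0.0) for v in cells)


@dataclass(frozen=True)
class Pop2x2Result:
    cells: Tuple[float, float, float, float]
    dn: float
    ds: float
    ev: float
    alpha: float
    protective_level: Optional[int]


def pop_measures_2x2(s: TwoByTwoScenario) -> Pop2x2Result:
    """Population DN, DS and EV via the closed 2x2 forms on probabilities."""
    cells = cells_from_scenario(s)
    m = measures_from_2x2(TwoByTwoTable(*cells))
    return Pop2x2Result(
        cells=cells,
        dn=m.dn1,
        ds=m.ds1,
        ev=m.ev,
        alpha=m.alpha if m.protective_level is not None else 0.0,
        protective_level=m.protective_level,
    )


# ---------------------------------------------------------------------------
# standard-normal factor, logistic link
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticNormalScenario:
    """X ~ N(0,1) with P(D | X=x) = expit(beta0 + beta1 x).

    ``beta1`` is the log odds ratio per SD of X; ``beta0`` is solved so
    that the marginal event probability integrates to ``p_d``.
    """

    beta1: float
    p_d: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_d < 1.0):
            raise InvalidBaselineError(f"p_d={self.p_d!r} must be in (0, 1)")
        if not math.isfinite(self.beta1):
            raise InfeasibleScenarioError("beta1 must be finite")


def solve_logistic_intercept(beta1: float, p_d: float) -> float:
    """Intercept beta0 with E_X[expit(beta0 + beta1 X)] = p_d for X ~ N(0,1)."""
    phi = stats.norm.pdf

    def marginal(b0: float) -> float:
        val, _ = integrate.quad(
            lambda x: expit(b0 + beta1 * x) * phi(x),
            -_NORM_RANGE, _NORM_RANGE,
            epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200,
        )
        return val - p_d

    span = abs(logit(p_d)) + abs(beta1) * _NORM_RANGE + 1.0
    return optimize.brentq(marginal, -span, span, xtol=1e-10)


@dataclass(frozen=True)
class LogisticNormalResult:
    beta0: float
    x_star: float
    alpha: float
    dn1: float
    dn2: float
    ds1: float
    ds2: float
    ev: float
    degenerate: bool = False


def pop_measures_logistic_normal(s: LogisticNormalScenario) -> LogisticNormalResult:
    """Population measures by adaptive quadrature against the normal density.

    The threshold x* solves P(D | x*) = P(D), i.e.
    x* = (logit(p_d) - beta0) / beta1; for beta1 > 0 values above x* are
    harmful, so alpha = 1 - Phi(x*).  The conditional expectations of the
    necessity/sufficiency kernels are integrated over the two sides of
    x*; EV uses the squared-deviation form, exact here because the model
    is calibrated by construction.  beta1 = 0 is degenerate: every
    measure is 0.
    """
    if s.beta1 == 0.0:
        return LogisticNormalResult(
            beta0=logit(s.p_d), x_star=math.nan, alpha=0.0,
            dn1=0.0, dn2=0.0, ds1=0.0, ds2=0.0, ev=0.0, degenerate=True,
        )
    beta0 = solve_logistic_intercept(s.beta1, s.p_d)
    x_star = (logit(s.p_d) - beta0) / s.beta1
    phi = stats.norm.pdf
    p = lambda x: expit(beta0 + s.beta1 * x)

    def q(fn, lo, hi):
        val, _ = integrate.quad(
            lambda x: fn(x) * phi(x), lo, hi,
            epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200,
        )
        return val

    if s.beta1 > 0:
        lo_protect, hi_protect = -_NORM_RANGE, x_star
        lo_harm, hi_harm = x_star, _NORM_RANGE
    else:
        lo_protect, hi_protect = x_star, _NORM_RANGE
        lo_harm, hi_harm = -_NORM_RANGE, x_star
    mass_protect = q(lambda x: 1.0, lo_protect, hi_protect)
    alpha = 1.0 - mass_protect

    dn_kernel = lambda x: (s.p_d - p(x)) / s.p_d
    ds_kernel = lambda x: (p(x) - s.p_d) / (1.0 - s.p_d)
    dn1 = math.sqrt(q(lambda x: dn_kernel(x) ** 2, lo_protect, hi_protect) / mass_protect)
    dn2 = q(dn_kernel, lo_protect, hi_protect) / mass_protect
    ds1 = math.sqrt(q(lambda x: ds_kernel(x) ** 2, lo_harm, hi_harm) / alpha)
    ds2 = q(ds_kernel, lo_harm, hi_harm) / alpha
    ev = q(lambda x: (p(x) - s.p_d) ** 2, -_NORM_RANGE, _NORM_RANGE) / (
        s.p_d * (1.0 - s.p_d)
    )
    return LogisticNormalResult(
        beta0=beta0, x_star=x_star, alpha=alpha,
        dn1=dn1, dn2=dn2, ds1=ds1, ds2=ds2, ev=ev,
    )


# ---------------------------------------------------------------------------
# two-group exponential survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalScenario:
    """Two-point exponential mixture with a censoring design.

    The harmful level (probability ``alpha``) has hazard 1, the
    protective level hazard 1/``hr``; reciprocal hazard ratios are
    re-oriented on construction.  ``tau`` is the analysis horizon
    (``inf`` for uncensored follow-up); ``censoring`` one of
    ``{"none", "type1", "administrative"}``.
    """

    hr: float
    alpha: float
    tau: float = math.inf
    censoring: str = "none"

    def __post_init__(self) -> None:
        if self.hr <= 0 or math.isnan(self.hr):
            raise InfeasibleScenarioError("hr must be positive")
        if self.hr < 1.0:  # re-orient: swap which level is harmful
            object.__setattr__(self, "hr", 1.0 / self.hr)
            object.__setattr__(self, "alpha", 1.0 - self.alpha)
        if not (0.0 < self.alpha < 1.0):
            raise InfeasibleScenarioError(f"alpha={self.alpha!r} must be in (0, 1)")
        if self.tau <= 0 or math.isnan(self.tau):
            raise InfeasibleScenarioError("tau must be positive (inf allowed)")
        if self.censoring not in ("none", "type1", "administrative"):
            raise InfeasibleScenarioError(f"unknown censoring {self.censoring!r}")
        if self.censoring != "none" and math.isinf(self.tau):
            raise InfeasibleScenarioError("censored designs need a finite tau")


@dataclass(frozen=True)
class SurvivalPopResult:
    dn: float
    ds: float
    ev: float
    pct_censored: float
    tau: float
    censoring: str


def pop_measures_survival(s: SurvivalScenario) -> SurvivalPopResult:
    """Population DN(tau), DS(tau), EV(tau) and the censoring percentage.

    The per-time kernels for a dichotomous factor reduce to single
    values (both measure variants coincide):

        DN_t = (F(t) - F_p(t)) / F(t),   DS_t = 1 - S_h(t)/S(t),

    integrated against the marginal event density f and normalised by
    the event mass on (0, tau].  The sufficiency kernel is written as a
    survival ratio, which stays numerically stable into the far tail
    where both 1 - F(t) and S_h(t) underflow at different rates.  Type I
    and administrative censoring share the same population measures at a
    given tau (the horizon, not the censoring pattern, determines them);
    they differ only in the reported censoring percentage:
    P(T > tau) under type I, E[min(T, tau)]/tau under administrative.
    """
    hr, alpha, tau = s.hr, s.alpha, s.tau

    S_h = lambda t: math.exp(-t)
    S_p = lambda t: math.exp(-t / hr)
    S = lambda t: alpha * S_h(t) + (1.0 - alpha) * S_p(t)
    F_p = lambda t: -math.expm1(-t / hr)
    F = lambda t: 1.0 - S(t)
    f = lambda t: alpha * math.exp(-t) + (1.0 - alpha) * math.exp(-t / hr) / hr

    def dn_t(t: float) -> float:
        # (F - F_p)/F = alpha (F_h - F_p)/F with F_h = -expm1(-t)
        F_h = -math.expm1(-t)
        return alpha * (F_h - F_p(t)) / F(t)

    def ds_t(t: float) -> float:
        # 1 - S_h/S = 1 - 1 / (alpha + (1-alpha) exp(t (1 - 1/hr)))
        expo = t * (1.0 - 1.0 / hr)
        if expo > 700.0:  # S_h/S underflows; kernel saturates at 1
            return 1.0
        return 1.0 - 1.0 / (alpha + (1.0 - alpha) * math.exp(expo))

    def q(fn) -> float:
        val, _ = integrate.quad(
            fn, 0.0, tau, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400
        )
        return val

    if hr == 1.0:
        dn = ds = ev = 0.0
    else:
        event_mass = q(f)
        dn = q(lambda t: dn_t(t) * f(t)) / event_mass
        ds = q(lambda t: ds_t(t) * f(t)) / event_mass
        num = q(
            lambda t: (
                alpha * (1.0 - S_h(t)) * S_h(t)
                + (1.0 - alpha) * F_p(t) * S_p(t)
            )
            * f(t)
        )
        den = q(lambda t: F(t) * S(t) * f(t))
        ev = 1.0 - num / den

    if s.censoring == "none":
        pct = 0.0
    elif s.censoring == "type1":
        pct = 100.0 * S(tau)
    else:  # administrative: uniform entry over (0, tau)
        pct = 100.0 * q(S) / tau
    return SurvivalPopResult(
        dn=dn, ds=ds, ev=ev, pct_censored=pct, tau=tau, censoring=s.censoring
    )
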