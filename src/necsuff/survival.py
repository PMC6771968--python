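"""Degrees of necessity and sufficiency for right-censored survival outcomes.

The binary-outcome measures generalise by comparing the conditional
cumulative incidence F(t | x) with the unconditional F(t) at every time:
at a fixed t the situation is exactly the dichotomous one, and the
overall measures average the per-time values over the event-time
distribution.  In a sample with distinct event times t_(1) < ... < t_(m)
and d_j events at t_(j),

    DN1 = w^-1 sum_j G(t_(j)^-)^-1 d_j DN1_{t_(j)},
    w   = sum_j G(t_(j)^-)^-1 d_j,

where DN1_t is the root-mean-square necessity kernel over subjects with
F(t|x_i) < F(t), and G is the Kaplan-Meier estimate of the censoring
("potential follow-up") distribution, obtained by reversing the event
indicator.  The reciprocal weights compensate the thinning of observed
events by earlier censoring, which makes the estimates robust to
administrative censoring before the horizon tau.  DS and the second
(mean-kernel) variants are analogous.  Explained variation follows
Schemper and Henderson: the relative reduction in mean absolute
predictive inaccuracy when conditional survival curves replace the
unconditional one, averaged over event times with the same weights.

All estimates depend on observation times only through their ranks, so
any strictly increasing transformation of the time scale leaves them
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .binary import MeasureEstimates
from .errors import (
    DegenerateTimeError,
    EstimationImpossibleError,
    NoEventsError,
)

__all__ = [
    "SurvivalSample",
    "SurvivalCurves",
    "TimepointMeasures",
    "km_cdf",
    "censoring_km",
    "dn_ds_at_time",
    "dn_ds_survival",
    "sh_explained_variation",
    "survival_measures",
    "per_time_table",
    "stratified_km_curves",
    "cox_cdf_adapter",
    "curves_from_matrix",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored observations: times, 0/1 event indicators, covariates."""

    times: np.ndarray
    events: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events)
        if t.ndim != 1 or t.size == 0:
            raise NoEventsError("times must be a non-empty 1-d sequence")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise NoEventsError("all observation times must be positive finite")
        if e.shape != t.shape or not np.isin(e, (0, 1)).all():
            raise NoEventsError("events must be 0/1 indicators matching times")
        if not e.any():
            raise NoEventsError("sample contains no events")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e.astype(int))
        if self.covariates is not None:
            cov = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(cov) != t.size:
                raise NoEventsError("covariates must have one row per subject")
            object.__setattr__(self, "covariates", cov)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SurvivalCurves:
    """Unconditional and conditional cumulative-incidence steps at event times.

    ``F_cond`` holds one row per *covariate profile*; ``subject_profiles``
    maps each subject to a row.  When it is ``None`` every subject has
    their own row (k = n).  Compressing identical profiles (for example
    the two arms of a dichotomous factor) keeps memory linear in the
    number of distinct profiles rather than subjects.
    """

    event_times: np.ndarray       # (m,) strictly increasing
    d: np.ndarray                 # (m,) events per time
    F_uncond: np.ndarray          # (m,)
    F_cond: np.ndarray            # (k, m)
    G_inv_weights: np.ndarray     # (m,) reverse-KM reciprocals at t_(j)^-
    subject_profiles: Optional[np.ndarray] = None  # (n,) row index per subject

    def __post_init__(self) -> None:
        et = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(et) <= 0):
            raise EstimationImpossibleError("event times must be strictly increasing")
        F = np.asarray(self.F_uncond, dtype=float)
        Fc = np.atleast_2d(np.asarray(self.F_cond, dtype=float))
        if F.shape != et.shape or Fc.shape[1] != et.size:
            raise EstimationImpossibleError("curve shapes do not match event times")
        tol = 1e-9
        if F.min() < -tol or F.max() > 1 + tol or np.any(np.diff(F) < -tol):
            raise EstimationImpossibleError("F_uncond must be nondecreasing in [0, 1]")
        if Fc.min() < -tol or Fc.max() > 1 + tol or np.any(np.diff(Fc, axis=1) < -tol):
            raise EstimationImpossibleError("each F_cond row must be nondecreasing in [0, 1]")
        w = np.asarray(self.G_inv_weights, dtype=float)
        if w.shape != et.shape or np.any(w < 1 - tol):
            raise EstimationImpossibleError("weights must be >= 1, one per event time")
        object.__setattr__(self, "event_times", et)
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        object.__setattr__(self, "F_uncond", np.clip(F, 0.0, 1.0))
        object.__setattr__(self, "F_cond", np.clip(Fc, 0.0, 1.0))
        object.__setattr__(self, "G_inv_weights", np.maximum(w, 1.0))
        if self.subject_profiles is not None:
            sp = np.asarray(self.subject_profiles, dtype=int)
            if sp.min() < 0 or sp.max() >= Fc.shape[0]:
                raise EstimationImpossibleError("subject_profiles out of range")
            object.__setattr__(self, "subject_profiles", sp)

    @property
    def n_profiles(self) -> int:
        return self.F_cond.shape[0]

    @property
    def n_subjects(self) -> int:
        if self.subject_profiles is None:
            return self.F_cond.shape[0]
        return self.subject_profiles.size

    @property
    def profile_counts(self) -> np.ndarray:
        """Number of subjects carrying each conditional-curve row."""
        if self.subject_profiles is None:
            return np.ones(self.F_cond.shape[0])
        return np.bincount(self.subject_profiles, minlength=self.F_cond.shape[0]).astype(float)


@dataclass(frozen=True)
class TimepointMeasures:
    """DN/DS kernels aggregated at a single time point."""

    dn1: float
    ds1: float
    dn2: float
    ds2: float
    n_less: float
    n_greater: float


# ---------------------------------------------------------------------------
# product-limit building blocks
# ---------------------------------------------------------------------------

def km_cdf(sample: SurvivalSample) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kaplan-Meier cumulative incidence at the distinct event times.

    Returns ``(event_times, d, F)`` with ``F`` right-continuous, i.e.
    evaluated including the deaths at each event time.
    """
    if not sample.events.any():
        raise NoEventsError("sample contains no events")
    event_times, d = np.unique(sample.times[sample.events == 1], return_counts=True)
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, sample.events)
    S = kmf.survival_function_at_times(event_times).to_numpy()
    return event_times, d.astype(float), 1.0 - S


def censoring_km(
    sample: SurvivalSample,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse Kaplan-Meier estimate of the censoring distribution.

    The product-limit estimator is applied with the meaning of the event
    indicator reversed.  At tied times, events are removed from the risk
    set before censorings occur, and the weight attached to an event
    time t_(j) is the *left limit* G(t_(j)^-)^-1, so it never conditions
    on censorings tied to t_(j).  This guarantees finite weights >= 1 at
    every event time; beyond the last censoring G stays at its final
    value.

    Returns ``(times, G, weights)``: the distinct observation times with
    the value of G *just after* each, and the weights 1/G(t_(j)^-)
    aligned with the distinct event times of :func:`km_cdf`.
    """
    order_times, idx = np.unique(sample.times, return_inverse=True)
    n = len(sample)
    d_at = np.bincount(idx, weights=sample.events, minlength=order_times.size)
    c_at = np.bincount(idx, weights=1 - sample.events, minlength=order_times.size)
    at_risk = n - np.concatenate(([0.0], np.cumsum(d_at + c_at)[:-1]))
    risk_for_cens = at_risk - d_at  # events leave the risk set first
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(c_at > 0, 1.0 - c_at / risk_for_cens, 1.0)
    G = np.cumprod(factors)

    event_times = np.unique(sample.times[sample.events == 1])
    # G just before t_(j): product of factors at strictly earlier times
    pos = np.searchsorted(order_times, event_times) - 1
    G_left = np.where(pos >= 0, G[np.maximum(pos, 0)], 1.0)
    return order_times, G, 1.0 / G_left


# ---------------------------------------------------------------------------
# per-time kernels
# ---------------------------------------------------------------------------

def dn_ds_at_time(
    F_t: float,
    F_cond_t: Sequence[float],
    counts: Optional[Sequence[float]] = None,
) -> TimepointMeasures:
    """Necessity/sufficiency kernels at one time point.

    ``F_t`` is the unconditional cumulative incidence, ``F_cond_t`` the
    conditional incidences (one per profile, with optional subject
    ``counts``).  Subjects strictly below ``F_t`` feed the necessity
    kernel (F_t - F_i)/F_t, subjects strictly above the sufficiency
    kernel (F_i - F_t)/(1 - F_t); an empty side yields 0.
    """
    if not (0.0 < F_t < 1.0):
        raise DegenerateTimeError(f"F(t)={F_t!r} must be strictly inside (0, 1)")
    Fc = np.asarray(F_cond_t, dtype=float)
    w = np.ones_like(Fc) if counts is None else np.asarray(counts, dtype=float)
    less = Fc < F_t
    greater = Fc > F_t
    n_less = float(w[less].sum())
    n_greater = float(w[greater].sum())
    dn1 = dn2 = 0.0
    if n_less > 0:
        k = (F_t - Fc[less]) / F_t
        dn1 = float(np.sqrt(np.sum(w[less] * k**2) / n_less))
        dn2 = float(np.sum(w[less] * k) / n_less)
    ds1 = ds2 = 0.0
    if n_greater > 0:
        k = (Fc[greater] - F_t) / (1.0 - F_t)
        ds1 = float(np.sqrt(np.sum(w[greater] * k**2) / n_greater))
        ds2 = float(np.sum(w[greater] * k) / n_greater)
    return TimepointMeasures(dn1, ds1, dn2, ds2, n_less, n_greater)


def _per_time_components(curves: SurvivalCurves, tau: Optional[float]):
    """Vectorised kernels at every usable event time <= tau."""
    if tau is None:
        keep = np.ones(curves.event_times.size, dtype=bool)
    else:
        keep = curves.event_times <= tau
    if not keep.any():
        raise EstimationImpossibleError("no event times at or before tau")
    F = curves.F_uncond[keep]
    Fc = curves.F_cond[:, keep]
    w = curves.G_inv_weights[keep] * curves.d[keep]
    counts = curves.profile_counts[:, None]

    less = Fc < F[None, :]
    greater = Fc > F[None, :]
    n_less = (counts * less).sum(axis=0)
    n_greater = (counts * greater).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        k_dn = np.where(less, (F[None, :] - Fc) / F[None, :], 0.0)
        k_ds = np.where(greater, (Fc - F[None, :]) / (1.0 - F[None, :]), 0.0)
    sum_dn = (counts * k_dn).sum(axis=0)
    sum_dn_sq = (counts * k_dn**2).sum(axis=0)
    sum_ds = (counts * k_ds).sum(axis=0)
    sum_ds_sq = (counts * k_ds**2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        dn1_t = np.where(n_less > 0, np.sqrt(sum_dn_sq / np.maximum(n_less, 1e-300)), 0.0)
        dn2_t = np.where(n_less > 0, sum_dn / np.maximum(n_less, 1e-300), 0.0)
        ds1_t = np.where(n_greater > 0, np.sqrt(sum_ds_sq / np.maximum(n_greater, 1e-300)), 0.0)
        ds2_t = np.where(n_greater > 0, sum_ds / np.maximum(n_greater, 1e-300), 0.0)
    return keep, F, w, n_less, n_greater, dn1_t, dn2_t, ds1_t, ds2_t


def dn_ds_survival(
    curves: SurvivalCurves,
    tau: Optional[float] = None,
    drop_empty: bool = True,
) -> MeasureEstimates:
    """Overall DN and DS as weighted averages over event times up to tau.

    Weights are d_j / G(t_(j)^-).  Event times whose informative set is
    empty carry no information about the affected measure; by default
    (``drop_empty=True``) they are removed from both the numerator and
    the denominator of that measure (DN and DS renormalised separately),
    mirroring the conditional-expectation definition.  With
    ``drop_empty=False`` they enter as zeros, diluting the average.

    ``tau`` defaults to the largest event time; no extrapolation beyond
    the observed follow-up is attempted.  The returned ``ev`` is NaN;
    use :func:`sh_explained_variation` or :func:`survival_measures` for
    explained variation.  ``alpha`` is the weighted average share of
    subjects on the harmful side; ``n_less``/``n_greater`` report the
    weighted-average informative-set sizes.
    """
    (_, _, w, n_less, n_greater,
     dn1_t, dn2_t, ds1_t, ds2_t) = _per_time_components(curves, tau)

    def _avg(values: np.ndarray, usable: np.ndarray) -> float:
        if drop_empty:
            if not usable.any():
                return 0.0
            return float(np.sum(w[usable] * values[usable]) / np.sum(w[usable]))
        return float(np.sum(w * values) / np.sum(w))

    dn_ok = n_less > 0
    ds_ok = n_greater > 0
    n = curves.n_subjects
    return MeasureEstimates(
        dn1=_avg(dn1_t, dn_ok),
        dn2=_avg(dn2_t, dn_ok),
        ds1=_avg(ds1_t, ds_ok),
        ds2=_avg(ds2_t, ds_ok),
        ev=float("nan"),
        alpha=float(np.sum(w * n_greater / n) / np.sum(w)),
        n_less=int(round(np.sum(w * n_less) / np.sum(w))),
        n_greater=int(round(np.sum(w * n_greater) / np.sum(w))),
    )


def per_time_table(curves: SurvivalCurves, tau: Optional[float] = None) -> pd.DataFrame:
    """Per-event-time diagnostics: kernels, weights and set sizes."""
    (keep, F, w, n_less, n_greater,
     dn1_t, dn2_t, ds1_t, ds2_t) = _per_time_components(curves, tau)
    return pd.DataFrame(
        {
            "time": curves.event_times[keep],
            "d": curves.d[keep],
            "F": F,
            "weight": w,
            "dn1_t": dn1_t,
            "dn2_t": dn2_t,
            "ds1_t": ds1_t,
            "ds2_t": ds2_t,
            "n_less": n_less,
            "n_greater": n_greater,
        }
    )


# ---------------------------------------------------------------------------
# Schemper-Henderson explained variation
# ---------------------------------------------------------------------------

def _group_inaccuracy(
    times: np.ndarray,
    events: np.ndarray,
    eval_times: np.ndarray,
    S_step: np.ndarray,
) -> np.ndarray:
    """Total absolute predictive inaccuracy of one curve for one group.

    At each evaluation time t, a subject observed beyond t contributes
    1 - S(t); a subject known dead by t contributes S(t); a subject
    censored at c <= t contributes the expectation over their unknown
    status, (S(t)/S(c)) (1 - S(t)) + (1 - S(t)/S(c)) S(t).  ``S_step``
    gives the survival values at ``eval_times`` (the step function's
    jump points).  Returns the group total at each evaluation time.
    """

    def step_at(u: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(eval_times, u, side="right") - 1
        return np.where(pos >= 0, S_step[np.maximum(pos, 0)], 1.0)

    t_sorted = np.sort(times)
    beyond = times.size - np.searchsorted(t_sorted, eval_times, side="right")

    dead_times = np.sort(times[events == 1])
    dead_by = np.searchsorted(dead_times, eval_times, side="right").astype(float)

    cens_times = np.sort(times[events == 0])
    cens_by = np.searchsorted(cens_times, eval_times, side="right")
    S_at_cens = step_at(cens_times)
    inv_sum = np.concatenate(([0.0], np.cumsum(1.0 / S_at_cens)))
    R = inv_sum[cens_by]  # sum of 1/S(c_i) over censorings by t

    S = S_step
    return beyond * (1.0 - S) + dead_by * S + cens_by * S + (1.0 - 2.0 * S) * S * R


def sh_explained_variation(
    sample: SurvivalSample,
    curves: SurvivalCurves,
    tau: Optional[float] = None,
) -> float:
    """Schemper-Henderson explained variation for survival outcomes.

    EV = 1 - sum_j w_j Mx(t_(j)) / sum_j w_j M(t_(j)) with
    w_j = d_j / G(t_(j)^-), where M and Mx are the mean absolute
    predictive inaccuracies of the unconditional and the conditional
    survival curves (see :func:`_group_inaccuracy` for the per-subject
    contributions).  A negative value (conditional curves predicting
    worse than the marginal) is clipped to 0 with a warning.
    """
    keep = (
        np.ones(curves.event_times.size, dtype=bool)
        if tau is None
        else curves.event_times <= tau
    )
    if not keep.any():
        raise EstimationImpossibleError("no event times at or before tau")
    et = curves.event_times[keep]
    w = (curves.G_inv_weights * curves.d)[keep]
    n = curves.n_subjects

    S_unc = 1.0 - curves.F_uncond[keep]
    M = _group_inaccuracy(sample.times, sample.events, et, S_unc) / n

    profiles = (
        np.arange(n) if curves.subject_profiles is None else curves.subject_profiles
    )
    Mx = np.zeros_like(M)
    for g in np.unique(profiles):
        mask = profiles == g
        S_g = 1.0 - curves.F_cond[g, keep]
        Mx += _group_inaccuracy(sample.times[mask], sample.events[mask], et, S_g)
    Mx /= n

    denom = float(np.sum(w * M))
    if denom <= 0:
        raise EstimationImpossibleError("unconditional inaccuracy is zero")
    ev = 1.0 - float(np.sum(w * Mx)) / denom
    if ev < 0:
        warnings.warn(
            "negative explained variation clipped to 0 "
            "(conditional curves predict worse than the marginal curve)",
            stacklevel=2,
        )
        ev = 0.0
    return ev


def survival_measures(
    sample: SurvivalSample,
    curves: SurvivalCurves,
    tau: Optional[float] = None,
    drop_empty: bool = True,
) -> MeasureEstimates:
    """DN, DS and Schemper-Henderson EV in one call."""
    base = dn_ds_survival(curves, tau=tau, drop_empty=drop_empty)
    ev = sh_explained_variation(sample, curves, tau=tau)
    return MeasureEstimates(
        dn1=base.dn1, dn2=base.dn2, ds1=base.ds1, ds2=base.ds2,
        ev=ev, alpha=base.alpha,
        n_less=base.n_less, n_greater=base.n_greater,
    )


# ---------------------------------------------------------------------------
# conditional-curve builders
# ---------------------------------------------------------------------------

def curves_from_matrix(
    sample: SurvivalSample,
    F_cond: np.ndarray,
    subject_profiles: Optional[np.ndarray] = None,
) -> SurvivalCurves:
    """Package a model-agnostic conditional-incidence matrix.

    Any estimator may supply ``F_cond`` (one row per profile, one column
    per distinct event time of ``sample``); the unconditional curve and
    censoring weights are computed from the sample itself.
    """
    event_times, d, F = km_cdf(sample)
    _, _, weights = censoring_km(sample)
    return SurvivalCurves(
        event_times=event_times,
        d=d,
        F_uncond=F,
        F_cond=F_cond,
        G_inv_weights=weights,
        subject_profiles=subject_profiles,
    )


def stratified_km_curves(
    sample: SurvivalSample, group: Sequence
) -> SurvivalCurves:
    """Conditional curves from group-wise Kaplan-Meier fits.

    Suitable for a single categorical covariate: each level gets its own
    product-limit curve, evaluated at the pooled event times.
    """
    group = np.asarray(group)
    if group.shape != sample.times.shape:
        raise EstimationImpossibleError("group must have one label per subject")
    event_times, d, F = km_cdf(sample)
    _, _, weights = censoring_km(sample)
    levels, profile_idx = np.unique(group, return_inverse=True)
    F_cond = np.empty((levels.size, event_times.size))
    for g, level in enumerate(levels):
        mask = group == level
        kmf = KaplanMeierFitter()
        kmf.fit(sample.times[mask], sample.events[mask])
        F_cond[g] = 1.0 - kmf.survival_function_at_times(event_times).to_numpy()
    return SurvivalCurves(
        event_times=event_times,
        d=d,
        F_uncond=F,
        F_cond=F_cond,
        G_inv_weights=weights,
        subject_profiles=profile_idx,
    )


def cox_cdf_adapter(
    sample: SurvivalSample,
    covariate_cols: Optional[Sequence[str]] = None,
    **cox_kwargs,
) -> SurvivalCurves:
    """Per-subject conditional curves from a proportional-hazards fit.

    Delegates to lifelines' Cox model (Breslow-type baseline) and
    evaluates each subject's predicted survival at every distinct event
    time.  Model convergence problems propagate as lifelines errors.
    """
    if sample.covariates is None:
        raise EstimationImpossibleError("sample has no covariates to fit")
    cov = sample.covariates
    if covariate_cols is not None:
        cov = cov[list(covariate_cols)]
    df = cov.copy()
    df["_time"] = sample.times
    df["_event"] = sample.events
    cph = CoxPHFitter(**cox_kwargs)
    cph.fit(df, duration_col="_time", event_col="_event")
    event_times, d, F = km_cdf(sample)
    _, _, weights = censoring_km(sample)
    sf = cph.predict_survival_function(cov, times=event_times)
    F_cond = 1.0 - sf.to_numpy().T  # (n, m)
    # guard tiny non-monotonicity from float evaluation of the baseline
    F_cond = np.maximum.accumulate(F_cond, axis=1)
    return SurvivalCurves(
        event_times=event_times,
        d=d,
        F_uncond=F,
        F_cond=F_cond,
        G_inv_weights=weights,
        subject_profiles=None,
    )
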