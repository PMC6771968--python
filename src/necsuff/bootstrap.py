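"""Percentile and BCa bootstrap confidence intervals for DN, DS and EV.

Replicates resample whole observation rows and re-run the full
model-fitting procedure, so the intervals reflect model-fitting
variability, not just plug-in noise.  A direction-consistency rule
guards against the protective/harmful partition silently flipping
inside a replicate: whenever the mean predicted probability over the
*original sample's* harmful range falls below the mean over its
protective range, that replicate's DN and DS (and hence EV) are set
to 0.

The BCa interval applies Efron's bias correction z0 (from the share of
replicates below the point estimate, with a mid-p adjustment for the
ties that the truncation rule piles up at 0) and an acceleration
constant from jackknife leave-one-out estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binary import binary_predictions, estimate_from_probs
from .errors import BootstrapFailureError, InsufficientDataError
from .survival import (
    SurvivalCurves,
    SurvivalSample,
    dn_ds_survival,
    sh_explained_variation,
)

__all__ = [
    "BootstrapResult",
    "bootstrap_ci",
    "bootstrap_ci_survival",
    "jackknife_acceleration",
    "bca_interval",
    "percentile_interval",
]

_MEASURES = ("dn1", "dn2", "ds1", "ds2", "ev")


@dataclass(frozen=True)
class BootstrapResult:
    """One measure's interval with its provenance."""

    point: float
    lower: float
    upper: float
    level: float
    method: str
    n_replicates: int
    n_truncated: int
    seed: Optional[int]


# ---------------------------------------------------------------------------
# interval machinery
# ---------------------------------------------------------------------------

def percentile_interval(replicates: np.ndarray, level: float):
    lo = (1.0 - level) / 2.0
    return tuple(np.quantile(replicates, [lo, 1.0 - lo]))


def jackknife_acceleration(
    data, statistic: Callable[[object], float]
) -> float:
    """Acceleration constant from leave-one-out estimates.

    ``data`` is indexable by row (DataFrame or ndarray); ``statistic``
    maps a row-subset to a scalar.  Returns 0 when the jackknife
    variance vanishes.
    """
    n = len(data)
    if n < 3:
        raise InsufficientDataError("jackknife needs at least 3 observations")
    theta = np.empty(n)
    for i in range(n):
        if isinstance(data, pd.DataFrame):
            sub = data.drop(data.index[i])
        else:
            sub = np.delete(np.asarray(data), i, axis=0)
        theta[i] = statistic(sub)
    return _acceleration_from_jackknife(theta)


def _acceleration_from_jackknife(theta: np.ndarray) -> float:
    dev = theta.mean() - theta
    ss = float(np.sum(dev**2))
    if ss == 0.0:
        return 0.0
    return float(np.sum(dev**3)) / (6.0 * ss**1.5)


def bca_interval(
    replicates: np.ndarray,
    point: float,
    level: float,
    acceleration: float,
):
    """Bias-corrected and accelerated percentile interval.

    The bias correction uses the mid-p share of replicates below the
    point estimate, (#{r < point} + #{r = point}/2)/B, which keeps z0
    finite when a point mass sits exactly at the estimate.
    """
    B = replicates.size
    frac = (np.sum(replicates < point) + 0.5 * np.sum(replicates == point)) / B
    frac = min(max(frac, 0.5 / B), 1.0 - 0.5 / B)
    z0 = stats.norm.ppf(frac)
    z = stats.norm.ppf([(1.0 - level) / 2.0, (1.0 + level) / 2.0])

    adj = z0 + (z0 + z) / (1.0 - acceleration * (z0 + z))
    quantiles = np.clip(stats.norm.cdf(adj), 0.0, 1.0)
    return tuple(np.quantile(replicates, quantiles))


def _build_results(
    reps: Dict[str, np.ndarray],
    points: Dict[str, float],
    jack: Optional[Dict[str, np.ndarray]],
    method: str,
    level: float,
    n_truncated: int,
    seed: Optional[int],
) -> Dict[str, BootstrapResult]:
    out = {}
    for name in _MEASURES:
        r = reps[name]
        if method == "percentile":
            lo, hi = percentile_interval(r, level)
        else:
            a = _acceleration_from_jackknife(jack[name]) if jack is not None else 0.0
            lo, hi = bca_interval(r, points[name], level, a)
        out[name] = BootstrapResult(
            point=points[name],
            lower=float(np.clip(lo, 0.0, 1.0)),
            upper=float(np.clip(hi, 0.0, 1.0)),
            level=level,
            method=method,
            n_replicates=r.size,
            n_truncated=n_truncated,
            seed=seed,
        )
    return out


# ---------------------------------------------------------------------------
# dichotomous outcomes
# ---------------------------------------------------------------------------

def _binary_estimates(probs: np.ndarray, outcomes: np.ndarray, ev_mode: str):
    preds = binary_predictions(probs, outcomes=outcomes)
    m = estimate_from_probs(preds, ev_mode=ev_mode)
    return {
        "dn1": m.dn1, "dn2": m.dn2, "ds1": m.ds1, "ds2": m.ds2, "ev": m.ev,
    }


def bootstrap_ci(
    data: pd.DataFrame,
    fit_predict: Callable[[pd.DataFrame], np.ndarray],
    outcome_col: str,
    B: int = 1000,
    method: str = "bca",
    level: float = 0.95,
    seed: Optional[int] = None,
    ev_mode: str = "indirect",
    max_failure_frac: float = 0.05,
) -> Dict[str, BootstrapResult]:
    """Bootstrap intervals for all five measures of a dichotomous outcome.

    Parameters
    ----------
    data : DataFrame
        One row per subject; must contain ``outcome_col`` with 0/1
        outcomes plus whatever columns ``fit_predict`` consumes.
    fit_predict : callable
        Re-runs the probability model on a (resampled) data frame and
        returns the per-row predicted event probabilities.  It is
        applied afresh to every replicate.
    B, method, level, seed
        Replicate count (>= 100), ``"percentile"`` or ``"bca"``,
        two-sided coverage, RNG seed.

    Failed replicate fits are redrawn; if more than
    ``max_failure_frac * B`` fail, the run aborts.
    """
    if B < 100:
        raise InsufficientDataError("B must be at least 100")
    if method not in ("percentile", "bca"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    data = data.reset_index(drop=True)
    n = len(data)
    y = data[outcome_col].to_numpy()

    probs0 = np.asarray(fit_predict(data), dtype=float)
    points = _binary_estimates(probs0, y, ev_mode)
    p_bar0 = y.mean()
    harm0 = probs0 > p_bar0
    prot0 = probs0 < p_bar0

    reps = {name: np.empty(B) for name in _MEASURES}
    n_truncated = 0
    failures = 0
    max_failures = int(max_failure_frac * B)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        df_b = data.iloc[idx]
        y_b = y[idx]
        try:
            if y_b.min() == y_b.max():
                raise ValueError("degenerate outcome in replicate")
            probs_b = np.asarray(fit_predict(df_b), dtype=float)
            est_b = _binary_estimates(probs_b, y_b, ev_mode)
        except Exception as exc:  # noqa: BLE001 - estimator is user code
            failures += 1
            if failures > max_failures:
                raise BootstrapFailureError(
                    f"estimator failed on more than {max_failure_frac:.0%} of "
                    f"replicates (last error: {exc})"
                ) from exc
            continue
        h, p = harm0[idx], prot0[idx]
        if h.any() and p.any() and probs_b[h].mean() < probs_b[p].mean():
            est_b = dict.fromkeys(_MEASURES, 0.0)
            n_truncated += 1
        for name in _MEASURES:
            reps[name][b] = est_b[name]
        b += 1

    jack = None
    if method == "bca":
        jack = {name: np.empty(n) for name in _MEASURES}
        for i in range(n):
            df_i = data.drop(index=i)
            probs_i = np.asarray(fit_predict(df_i), dtype=float)
            est_i = _binary_estimates(probs_i, np.delete(y, i), ev_mode)
            for name in _MEASURES:
                jack[name][i] = est_i[name]
    return _build_results(reps, points, jack, method, level, n_truncated, seed)


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------

def _survival_estimates(sample: SurvivalSample, curves: SurvivalCurves, tau):
    m = dn_ds_survival(curves, tau=tau)
    ev = sh_explained_variation(sample, curves, tau=tau)
    return {
        "dn1": m.dn1, "dn2": m.dn2, "ds1": m.ds1, "ds2": m.ds2, "ev": ev,
    }


def _mean_incidence(curves: SurvivalCurves, subjects: np.ndarray) -> float:
    """Weighted average conditional incidence over a subject subset."""
    w = curves.G_inv_weights * curves.d
    profiles = (
        subjects
        if curves.subject_profiles is None
        else curves.subject_profiles[subjects]
    )
    per_subject = curves.F_cond[profiles] @ w / w.sum()
    return float(per_subject.mean())


def bootstrap_ci_survival(
    sample: SurvivalSample,
    curve_builder: Callable[[SurvivalSample], SurvivalCurves],
    tau: Optional[float] = None,
    B: int = 1000,
    method: str = "bca",
    level: float = 0.95,
    seed: Optional[int] = None,
    max_failure_frac: float = 0.05,
) -> Dict[str, BootstrapResult]:
    """Bootstrap intervals for the survival measures.

    ``curve_builder`` rebuilds the conditional-incidence curves (for
    example a stratified-KM or Cox fit) on each resampled sample.  The
    direction rule carries over on the incidence scale: a replicate is
    zeroed when the censoring-weighted average conditional incidence
    over the original sample's harmful subjects falls below that over
    its protective subjects.
    """
    if B < 100:
        raise InsufficientDataError("B must be at least 100")
    if method not in ("percentile", "bca"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n = len(sample)

    curves0 = curve_builder(sample)
    points = _survival_estimates(sample, curves0, tau)
    w0 = curves0.G_inv_weights * curves0.d
    profiles0 = (
        np.arange(n)
        if curves0.subject_profiles is None
        else curves0.subject_profiles
    )
    subj_inc0 = curves0.F_cond[profiles0] @ w0 / w0.sum()
    overall0 = float(curves0.F_uncond @ w0 / w0.sum())
    harm0 = subj_inc0 > overall0
    prot0 = subj_inc0 < overall0

    def resample(idx: np.ndarray) -> SurvivalSample:
        cov = (
            None
            if sample.covariates is None
            else sample.covariates.iloc[idx].reset_index(drop=True)
        )
        return SurvivalSample(
            times=sample.times[idx], events=sample.events[idx], covariates=cov
        )

    def estimates_for(idx: np.ndarray, truncate: bool):
        sub = resample(idx)
        curves_b = curve_builder(sub)
        est = _survival_estimates(sub, curves_b, tau)
        if truncate:
            h, p = harm0[idx], prot0[idx]
            if h.any() and p.any():
                wb = curves_b.G_inv_weights * curves_b.d
                prof_b = (
                    np.arange(len(sub))
                    if curves_b.subject_profiles is None
                    else curves_b.subject_profiles
                )
                inc_b = curves_b.F_cond[prof_b] @ wb / wb.sum()
                if inc_b[h].mean() < inc_b[p].mean():
                    return dict.fromkeys(_MEASURES, 0.0), True
        return est, False

    reps = {name: np.empty(B) for name in _MEASURES}
    n_truncated = 0
    failures = 0
    max_failures = int(max_failure_frac * B)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            est_b, truncated = estimates_for(idx, truncate=True)
        except Exception as exc:  # noqa: BLE001
            failures += 1
            if failures > max_failures:
                raise BootstrapFailureError(
                    f"estimator failed on more than {max_failure_frac:.0%} of "
                    f"replicates (last error: {exc})"
                ) from exc
            continue
        n_truncated += truncated
        for name in _MEASURES:
            reps[name][b] = est_b[name]
        b += 1

    jack = None
    if method == "bca":
        jack = {name: np.empty(n) for name in _MEASURES}
        all_idx = np.arange(n)
        for i in range(n):
            est_i, _ = estimates_for(np.delete(all_idx, i), truncate=False)
            for name in _MEASURES:
                jack[name][i] = est_i[name]
    return _build_results(reps, points, jack, method, level, n_truncated, seed)
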