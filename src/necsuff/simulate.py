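"""Synthetic data generators and the simulation harness.

Three generator families mirror the population scenario families, so
that estimates on generated samples can be validated against the exact
calculators in :mod:`necsuff.population`:

* logistic-normal: X ~ N(0,1), outcome ~ Bernoulli(expit(b0 + b1 X));
* dichotomous 2x2: a multinomial draw from the scenario's cell
  probabilities;
* two-group exponential survival: harmful level (probability alpha)
  with hazard 1, protective with hazard 1/HR, censored not at all,
  at a fixed horizon tau (type I), or uniformly on (0, tau)
  (administrative censoring, i.e. staggered entry at constant rate).

Replicate RNG streams are derived from the base seed with
``numpy.random.SeedSequence(seed).spawn``, a counter-based scheme that
makes every replicate independently reproducible from ``(seed, index)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .binary import (
    TwoByTwoTable,
    binary_predictions,
    estimate_from_probs,
    measures_from_2x2,
)
from .bootstrap import bootstrap_ci
from .errors import InfeasibleScenarioError
from .population import (
    LogisticNormalScenario,
    SurvivalScenario,
    TwoByTwoScenario,
    cells_from_scenario,
    pop_measures_2x2,
    pop_measures_logistic_normal,
    pop_measures_survival,
    solve_logistic_intercept,
)
from .survival import SurvivalSample, stratified_km_curves, survival_measures

__all__ = [
    "SimulationDesign",
    "gen_logistic_normal",
    "gen_2x2",
    "gen_exponential_survival",
    "lung_cancer_fixture",
    "fit_logistic_probs",
    "logistic_fit_predict",
    "simulation_study",
]

Scenario = Union[LogisticNormalScenario, TwoByTwoScenario, SurvivalScenario]
_FAMILIES = ("logistic-normal", "two-by-two", "exponential-survival")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_logistic_normal(
    n: int, beta0: float, beta1: float, seed=None
) -> pd.DataFrame:
    """Sample (x, y, p_true) from the logistic-normal model."""
    rng = _rng(seed)
    x = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = rng.binomial(1, p)
    return pd.DataFrame({"x": x, "y": y, "p_true": p})


def gen_2x2(n: int, scenario: TwoByTwoScenario, seed=None) -> TwoByTwoTable:
    """Multinomial draw of n subjects from the scenario's cell probabilities."""
    rng = _rng(seed)
    a, b, c, d = rng.multinomial(n, cells_from_scenario(scenario))
    return TwoByTwoTable(a=float(a), b=float(b), c=float(c), d=float(d))


def gen_exponential_survival(
    n: int,
    hr: float,
    alpha: float,
    censoring: str = "none",
    tau: Optional[float] = None,
    seed=None,
) -> SurvivalSample:
    """Two-group exponential survival times with the scenario's censoring.

    The harmful group (indicator 1, probability ``alpha``) has hazard 1;
    the protective group hazard 1/``hr``.  ``censoring`` is ``"none"``,
    ``"type1"`` (all followed exactly ``tau``) or ``"administrative"``
    (follow-up uniform on (0, tau)).
    """
    if censoring not in ("none", "type1", "administrative"):
        raise InfeasibleScenarioError(f"unknown censoring {censoring!r}")
    if censoring != "none" and (tau is None or not math.isfinite(tau)):
        raise InfeasibleScenarioError("censored modes require a finite tau")
    rng = _rng(seed)
    harmful = rng.random(n) < alpha
    scale = np.where(harmful, 1.0, hr)  # mean of Exp(hazard) is 1/hazard
    T = rng.exponential(scale)
    if censoring == "none":
        times, events = T, np.ones(n, dtype=int)
    else:
        C = np.full(n, tau) if censoring == "type1" else rng.uniform(0.0, tau, n)
        times = np.minimum(T, C)
        events = (T <= C).astype(int)
    return SurvivalSample(
        times=times,
        events=events,
        covariates=pd.DataFrame({"group": harmful.astype(int)}),
    )


def lung_cancer_fixture() -> TwoByTwoTable:
    """The Swedish smoking / lung-cancer-death cohort (n = 12 664).

    33-year follow-up of 12 664 males; rows are died-from-lung-cancer
    vs otherwise, columns never/ever smoked.  Serves as the worked 2x2
    example throughout the package.
    """
    return TwoByTwoTable(a=8120.0, b=4331.0, c=36.0, d=177.0)


# ---------------------------------------------------------------------------
# logistic model fitting (the default estimator-spec)
# ---------------------------------------------------------------------------

def fit_logistic_probs(
    df: pd.DataFrame,
    covariate_cols: Sequence[str],
    outcome_col: str,
) -> np.ndarray:
    """Fitted probabilities from an (unpenalised) logistic regression."""
    X = sm.add_constant(df[list(covariate_cols)].to_numpy(), has_constant="add")
    y = df[outcome_col].to_numpy()
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return np.asarray(res.fittedvalues)


def logistic_fit_predict(covariate_cols: Sequence[str], outcome_col: str):
    """Estimator-spec closure for :func:`necsuff.bootstrap.bootstrap_ci`."""

    def _fit(df: pd.DataFrame) -> np.ndarray:
        return fit_logistic_probs(df, covariate_cols, outcome_col)

    return _fit


# ---------------------------------------------------------------------------
# the simulation loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationDesign:
    """A simulation: family, scenario parameters, sizes and base seed."""

    family: str
    scenario: Scenario
    n: int
    n_sim: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InfeasibleScenarioError(
                f"family must be one of {_FAMILIES}, got {self.family!r}"
            )

    def replicate_rngs(self):
        return [
            np.random.default_rng(s)
            for s in np.random.SeedSequence(self.seed).spawn(self.n_sim)
        ]


def _population_values(design: SimulationDesign) -> Dict[str, float]:
    if design.family == "logistic-normal":
        p = pop_measures_logistic_normal(design.scenario)
        return {"dn1": p.dn1, "dn2": p.dn2, "ds1": p.ds1, "ds2": p.ds2, "ev": p.ev}
    if design.family == "two-by-two":
        p = pop_measures_2x2(design.scenario)
        return {"dn1": p.dn, "dn2": p.dn, "ds1": p.ds, "ds2": p.ds, "ev": p.ev}
    p = pop_measures_survival(design.scenario)
    return {"dn1": p.dn, "dn2": p.dn, "ds1": p.ds, "ds2": p.ds, "ev": p.ev}


def _one_replicate(design: SimulationDesign, rng, bootstrap_B, method, level):
    """Generate, fit, estimate and (optionally) bootstrap one replicate."""
    sc = design.scenario
    if design.family == "logistic-normal":
        beta0 = solve_logistic_intercept(sc.beta1, sc.p_d)
        df = gen_logistic_normal(design.n, beta0, sc.beta1, rng)
        if bootstrap_B:
            ci = bootstrap_ci(
                df,
                logistic_fit_predict(["x"], "y"),
                outcome_col="y",
                B=bootstrap_B,
                method=method,
                level=level,
                seed=rng,
            )
            return {k: v.point for k, v in ci.items()}, ci
        probs = fit_logistic_probs(df, ["x"], "y")
        m = estimate_from_probs(binary_predictions(probs, outcomes=df["y"]))
    elif design.family == "two-by-two":
        table = gen_2x2(design.n, sc, rng)
        table.require_margins()
        m = measures_from_2x2(table)
    else:
        sample = gen_exponential_survival(
            design.n, sc.hr, sc.alpha,
            censoring=sc.censoring,
            tau=None if math.isinf(sc.tau) else sc.tau,
            seed=rng,
        )
        curves = stratified_km_curves(sample, sample.covariates["group"])
        tau = None if math.isinf(sc.tau) else sc.tau
        m = survival_measures(sample, curves, tau=tau)
    est = {"dn1": m.dn1, "dn2": m.dn2, "ds1": m.ds1, "ds2": m.ds2, "ev": m.ev}
    return est, None


def simulation_study(
    design: SimulationDesign,
    bootstrap_B: Optional[int] = None,
    method: str = "bca",
    level: float = 0.95,
) -> pd.DataFrame:
    """Run the full generate/fit/estimate loop and summarise it.

    Returns one row per measure with the population value, the quartiles
    of the bias (sample minus population), and, when ``bootstrap_B`` is
    set, the empirical coverage of the population value and the mean
    interval width.  Replicates whose fit fails are tallied in
    ``result.attrs["n_failures"]`` and skipped.  Interval bootstrapping
    is currently wired for the logistic-normal family, the one used for
    the coverage studies.
    """
    if bootstrap_B and design.family != "logistic-normal":
        raise InfeasibleScenarioError(
            "interval simulation is implemented for the logistic-normal family"
        )
    pop = _population_values(design)
    estimates = []
    intervals = []
    n_failures = 0
    for rng in design.replicate_rngs():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est, ci = _one_replicate(design, rng, bootstrap_B, method, level)
        except Exception:  # noqa: BLE001 - tally and continue
            n_failures += 1
            continue
        estimates.append(est)
        intervals.append(ci)

    rows = []
    for name in ("dn1", "dn2", "ds1", "ds2", "ev"):
        bias = np.array([e[name] - pop[name] for e in estimates])
        row = {
            "measure": name,
            "population": pop[name],
            "n_ok": bias.size,
            "bias_q1": float(np.quantile(bias, 0.25)),
            "bias_median": float(np.median(bias)),
            "bias_q3": float(np.quantile(bias, 0.75)),
            "bias_mean": float(np.mean(bias)),
        }
        if bootstrap_B:
            lo = np.array([ci[name].lower for ci in intervals])
            hi = np.array([ci[name].upper for ci in intervals])
            row["coverage"] = float(
                np.mean((lo <= pop[name]) & (pop[name] <= hi))
            )
            row["mean_width"] = float(np.mean(hi - lo))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("measure")
    out.attrs["n_failures"] = n_failures
    return out
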