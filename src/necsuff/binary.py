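"""Degrees of necessity and sufficiency for dichotomous outcomes.

A *cause* (a level of a prognostic factor X) is necessary for an event D
to the degree that, without it, the event probability drops towards 0;
it is sufficient to the degree that, with it, the event probability rises
towards 1.  Writing p(x) = P(D | X = x) and p = P(D), factor levels with
p(x) < p are *protective*, levels with p(x) > p are *harmful*, and the
measures average the normalised departures of p(x) from p over each side:

    DN1 = sqrt( E[ ((p - p(X)) / p)^2         | p(X) < p ] )
    DS1 = sqrt( E[ ((p(X) - p) / (1 - p))^2   | p(X) > p ] )

with DN2/DS2 the un-squared (mean) variants.  Levels with p(x) = p are
non-informative and excluded.  All four measures live in [0, 1]; for a
dichotomous factor DN equals the classical attributable risk AR and DS
the reverse attributable risk AR*, and explained variation satisfies
EV = DN * DS exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateTableError,
    InvalidBaselineError,
    InvalidProbabilityError,
    UndefinedRatioError,
)

__all__ = [
    "BinaryPredictions",
    "TwoByTwoTable",
    "MeasureEstimates",
    "AttributableRisks",
    "PartialMeasures",
    "binary_predictions",
    "estimate_from_probs",
    "measures_from_2x2",
    "predictions_from_2x2",
    "attributable_risks",
    "relative_risk",
    "ev_decomposition",
    "partial_measures",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryPredictions:
    """Per-subject conditional event probabilities with a baseline.

    Attributes
    ----------
    probs : ndarray
        Estimated conditional event probabilities, one per subject,
        each in [0, 1].
    p_bar : float
        Baseline (unconditional) event probability, strictly in (0, 1).
    outcomes : ndarray or None
        Optional 0/1 outcome indicators, same length as ``probs``.
    """

    probs: np.ndarray
    p_bar: float
    outcomes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise InvalidProbabilityError(
                "probs must be a non-empty 1-d sequence of probabilities"
            )
        if np.any(~np.isfinite(probs)) or probs.min() < 0.0 or probs.max() > 1.0:
            raise InvalidProbabilityError(
                "all conditional probabilities must lie in [0, 1]"
            )
        object.__setattr__(self, "probs", probs)
        if not (0.0 < self.p_bar < 1.0):
            raise InvalidBaselineError(
                f"baseline probability p_bar={self.p_bar!r} must be in (0, 1)"
            )
        if self.outcomes is not None:
            out = np.asarray(self.outcomes)
            if out.shape != probs.shape:
                raise InvalidProbabilityError(
                    "outcomes must have the same length as probs"
                )
            if not np.isin(out, (0, 1)).all():
                raise InvalidProbabilityError("outcomes must be 0/1 indicators")
            object.__setattr__(self, "outcomes", out.astype(int))

    def __len__(self) -> int:
        return self.probs.size


def binary_predictions(
    probs: Sequence[float],
    p_bar: Optional[float] = None,
    outcomes: Optional[Sequence[int]] = None,
) -> BinaryPredictions:
    """Build a :class:`BinaryPredictions`, resolving the default baseline.

    When ``p_bar`` is not given it defaults to the mean of ``outcomes``
    if those are supplied (the model-free choice) and to the mean of
    ``probs`` otherwise; the two coincide for a calibrated model.
    """
    probs = np.asarray(probs, dtype=float)
    if p_bar is None:
        if outcomes is not None:
            p_bar = float(np.mean(outcomes))
        else:
            p_bar = float(np.mean(probs))
    return BinaryPredictions(probs=probs, p_bar=float(p_bar), outcomes=outcomes)


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 layout of a dichotomous factor X against a dichotomous outcome D.

    ``a`` = (X=0, no event), ``b`` = (X=1, no event),
    ``c`` = (X=0, event),    ``d`` = (X=1, event).
    Entries may be counts or population cell probabilities; all formulas
    are scale-invariant.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DegenerateTableError(f"cell {name}={v!r} must be >= 0")
        if self.n <= 0:
            raise DegenerateTableError("table total must be positive")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def require_margins(self) -> None:
        """Raise unless all four margins are nonzero."""
        margins = {
            "event (c+d)": self.c + self.d,
            "non-event (a+b)": self.a + self.b,
            "X=0 (a+c)": self.a + self.c,
            "X=1 (b+d)": self.b + self.d,
        }
        for name, value in margins.items():
            if value == 0:
                raise DegenerateTableError(f"zero margin: {name}")


@dataclass(frozen=True)
class MeasureEstimates:
    """DN/DS/EV estimates plus bookkeeping about the informative sets."""

    dn1: float
    dn2: float
    ds1: float
    ds2: float
    ev: float
    alpha: float
    n_less: int
    n_greater: int
    protective_level: Optional[int] = None
    ev_indirect: Optional[float] = None
    ev_direct: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "dn1": self.dn1,
            "dn2": self.dn2,
            "ds1": self.ds1,
            "ds2": self.ds2,
            "ev": self.ev,
            "alpha": self.alpha,
            "n_less": self.n_less,
            "n_greater": self.n_greater,
            "protective_level": self.protective_level,
        }


@dataclass(frozen=True)
class AttributableRisks:
    """Attributable risk AR and reverse attributable risk AR*."""

    ar: float
    ar_star: float
    protective_level: Optional[int] = None


@dataclass(frozen=True)
class PartialMeasures:
    """Componentwise differences between nested-model measure estimates."""

    dn1: float
    dn2: float
    ds1: float
    ds2: float
    ev: float


# ---------------------------------------------------------------------------
# estimation from probability vectors
# ---------------------------------------------------------------------------

def estimate_from_probs(
    preds: BinaryPredictions,
    ev_mode: str = "indirect",
    tie_tol: float = 0.0,
) -> MeasureEstimates:
    """Estimate DN1, DN2, DS1, DS2, EV and alpha from predicted probabilities.

    Parameters
    ----------
    preds : BinaryPredictions
        Conditional probabilities and baseline.
    ev_mode : {"indirect", "direct"}
        ``"indirect"`` is the plug-in of the predictive-inaccuracy form
        ``EV = 1 - mean(p_i (1 - p_i)) / (p (1 - p))``; ``"direct"``
        uses the squared-deviation form ``mean((p_i - p)^2) / (p (1 - p))``.
        The two coincide when the model is calibrated (mean(p_i) = p);
        both are always reported in the result.
    tie_tol : float
        Absolute tolerance within which ``p_i`` counts as equal to the
        baseline and is excluded as non-informative (default: exact ties
        only).

    Notes
    -----
    Measures over an empty informative set are 0.  The indirect EV can be
    negative for a badly miscalibrated model; the headline ``ev`` is then
    clipped at 0 with a warning while ``ev_indirect`` keeps the raw value.
    """
    if ev_mode not in ("indirect", "direct"):
        raise ValueError(f"unknown ev_mode {ev_mode!r}")
    p = preds.probs
    p_bar = preds.p_bar
    diff = p - p_bar
    less = diff < -tie_tol
    greater = diff > tie_tol
    n_less = int(less.sum())
    n_greater = int(greater.sum())

    dn1 = dn2 = 0.0
    if n_less:
        k = (p_bar - p[less]) / p_bar
        dn1 = math.sqrt(float(np.mean(k**2)))
        dn2 = float(np.mean(k))
    ds1 = ds2 = 0.0
    if n_greater:
        k = (p[greater] - p_bar) / (1.0 - p_bar)
        ds1 = math.sqrt(float(np.mean(k**2)))
        ds2 = float(np.mean(k))

    denom = p_bar * (1.0 - p_bar)
    ev_indirect = 1.0 - float(np.mean(p * (1.0 - p))) / denom
    ev_direct = float(np.mean(diff**2)) / denom
    ev = ev_indirect if ev_mode == "indirect" else ev_direct
    if not 0.0 <= ev <= 1.0:
        warnings.warn(
            f"{ev_mode} EV of {ev:.4g} is outside [0, 1] (miscalibrated "
            "predictions); clipping, see ev_indirect/ev_direct for raw values",
            stacklevel=2,
        )
        ev = min(max(ev, 0.0), 1.0)

    return MeasureEstimates(
        dn1=dn1,
        dn2=dn2,
        ds1=ds1,
        ds2=ds2,
        ev=ev,
        alpha=n_greater / len(preds),
        n_less=n_less,
        n_greater=n_greater,
        ev_indirect=ev_indirect,
        ev_direct=ev_direct,
    )


# ---------------------------------------------------------------------------
# closed forms for a single dichotomous factor
# ---------------------------------------------------------------------------

def measures_from_2x2(table: TwoByTwoTable) -> MeasureEstimates:
    """Closed-form DN, DS and EV for a 2x2 table.

    The level with the lower event rate is protective.  For ad - bc > 0
    (X=0 protective):

        DN = (ad - bc) / ((a+c)(c+d)),   DS = (ad - bc) / ((a+b)(b+d))

    with the symmetric formulas when X=1 is protective, and
    EV = DN * DS exactly.  DN1 = DN2 and DS1 = DS2 for a dichotomous
    factor, so single values are returned for both variants.
    """
    table.require_margins()
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    det = a * d - b * c
    if det > 0:
        protective = 0
        dn = det / ((a + c) * (c + d))
        ds = det / ((a + b) * (b + d))
        alpha = (b + d) / n
        n_less, n_greater = a + c, b + d
    elif det < 0:
        protective = 1
        dn = -det / ((b + d) * (c + d))
        ds = -det / ((a + b) * (a + c))
        alpha = (a + c) / n
        n_less, n_greater = b + d, a + c
    else:
        return MeasureEstimates(
            dn1=0.0, dn2=0.0, ds1=0.0, ds2=0.0, ev=0.0, alpha=0.0,
            n_less=0, n_greater=0, protective_level=None,
        )
    return MeasureEstimates(
        dn1=dn,
        dn2=dn,
        ds1=ds,
        ds2=ds,
        ev=dn * ds,
        alpha=alpha,
        n_less=int(round(n_less)),
        n_greater=int(round(n_greater)),
        protective_level=protective,
    )


def predictions_from_2x2(table: TwoByTwoTable) -> BinaryPredictions:
    """Expand an integer-count 2x2 table into per-subject predictions.

    Each subject receives their group's conditional event rate; the
    baseline is the marginal event rate.  Feeding the result through
    :func:`estimate_from_probs` reproduces :func:`measures_from_2x2`.
    """
    table.require_margins()
    a, b, c, d = (int(round(v)) for v in (table.a, table.b, table.c, table.d))
    p0 = c / (a + c)
    p1 = d / (b + d)
    probs = np.repeat([p0, p1], [a + c, b + d])
    outcomes = np.concatenate(
        [np.repeat([0, 1], [a, c]), np.repeat([0, 1], [b, d])]
    )
    return BinaryPredictions(
        probs=probs, p_bar=(c + d) / table.n, outcomes=outcomes
    )


def attributable_risks(table: TwoByTwoTable) -> AttributableRisks:
    """Attributable risk and reverse attributable risk of a 2x2 table.

    AR = (P(D) - P(D | protective)) / P(D) coincides with DN, and
    AR* = (P(not D) - P(not D | harmful)) / P(not D) with DS, with the
    same direction resolution as :func:`measures_from_2x2`; hence
    AR * AR* equals the table's EV.
    """
    m = measures_from_2x2(table)
    return AttributableRisks(
        ar=m.dn1, ar_star=m.ds1, protective_level=m.protective_level
    )


def relative_risk(table: TwoByTwoTable) -> float:
    """Event-rate ratio of the harmful over the protective level."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0:
        raise UndefinedRatioError("both factor levels must be observed")
    rate0 = c / (a + c)
    rate1 = d / (b + d)
    det = a * d - b * c
    if det >= 0:  # X=0 protective (or no association)
        if rate0 == 0:
            raise UndefinedRatioError("protective-level event rate is zero")
        return rate1 / rate0
    if rate1 == 0:
        raise UndefinedRatioError("protective-level event rate is zero")
    return rate0 / rate1


# ---------------------------------------------------------------------------
# explained-variation decomposition and partial measures
# ---------------------------------------------------------------------------

def ev_decomposition(dn1: float, ds1: float, alpha: float, p_bar: float) -> float:
    """Recompose EV from DN1, DS1 and the harmful-level probability.

        EV = (1 - alpha) * odds(D) * DN1^2 + alpha * odds(not D) * DS1^2

    where odds(D) = p / (1 - p).  The identity is exact when EV is taken
    in its squared-deviation form and the predictions are calibrated.
    """
    if not (0.0 < p_bar < 1.0):
        raise InvalidBaselineError(f"p_bar={p_bar!r} must be in (0, 1)")
    for name, v in (("dn1", dn1), ("ds1", ds1), ("alpha", alpha)):
        if not (0.0 <= v <= 1.0):
            raise NecSuffRangeError(name, v)
    odds = p_bar / (1.0 - p_bar)
    return (1.0 - alpha) * odds * dn1**2 + alpha / odds * ds1**2


class NecSuffRangeError(InvalidProbabilityError):
    def __init__(self, name: str, value: float):
        super().__init__(f"{name}={value!r} must lie in [0, 1]")


def partial_measures(
    full: MeasureEstimates, reduced: MeasureEstimates
) -> PartialMeasures:
    """Gain in each measure when moving from a reduced to a full model.

    Both estimates must come from the same subjects and outcome.  Sample
    partials can be negative; they are returned unchanged with a warning.
    """
    out = PartialMeasures(
        dn1=full.dn1 - reduced.dn1,
        dn2=full.dn2 - reduced.dn2,
        ds1=full.ds1 - reduced.ds1,
        ds2=full.ds2 - reduced.ds2,
        ev=full.ev - reduced.ev,
    )
    if min(out.dn1, out.dn2, out.ds1, out.ds2, out.ev) < 0:
        warnings.warn(
            "negative partial measure: the added factor reduced an estimate",
            stacklevel=2,
        )
    return out
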