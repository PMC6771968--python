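"""Exception hierarchy for necsuff.

All input-validation failures raise subclasses of :class:`NecSuffError`
(itself a ``ValueError``), so callers can catch either the specific
condition or anything the package considers a bad input.
"""


class NecSuffError(ValueError):
    """Base class for all necsuff input/estimation errors."""


class InvalidBaselineError(NecSuffError):
    """Baseline event probability is not strictly inside (0, 1)."""


class InvalidProbabilityError(NecSuffError):
    """A conditional probability lies outside [0, 1]."""


class DegenerateTableError(NecSuffError):
    """A 2x2 table has a zero margin, making a probability inestimable."""


class UndefinedRatioError(NecSuffError):
    """Relative risk undefined because a denominator event rate is zero."""


class NoEventsError(NecSuffError):
    """A survival sample contains no events."""


class DegenerateTimeError(NecSuffError):
    """Unconditional cumulative incidence is 0 or 1 at the requested time."""


class EstimationImpossibleError(NecSuffError):
    """No usable event times remain below the requested horizon."""


class InfeasibleScenarioError(NecSuffError):
    """No admissible joint distribution exists for the scenario parameters."""


class InsufficientDataError(NecSuffError):
    """Too few observations for the requested computation."""


class BootstrapFailureError(NecSuffError):
    """Estimator failed on too large a fraction of bootstrap replicates."""
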