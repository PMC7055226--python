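"""Exception hierarchy for cgtcal.

Every signalled failure mode has a dedicated class so callers (and the
CLI) can distinguish malformed input from internal errors.
"""


class CgtcalError(Exception):
    """Base class for all package errors."""


class ScheduleExhaustedError(CgtcalError):
    """A non-cycling deck schedule was drawn past its last card."""


class MalformedBlockError(CgtcalError):
    """A block was played with the wrong number of deck choices."""


class InvalidResponseError(CgtcalError):
    """A choice/estimate provider returned an unknown deck label or category."""


class InvalidCategoryError(CgtcalError):
    """An estimate category outside {MORE, SAME, LESS, DONT_KNOW}."""


class IncompleteSessionError(CgtcalError):
    """A session is missing a block payoff or estimate occasion it needs."""


class IncompleteCovariatesError(CgtcalError):
    """A participant lacks a covariate required by the model tables."""


class UndefinedCorrelationError(CgtcalError):
    """Pearson r requested on constant or too-short input."""


class RankDeficientDesignError(CgtcalError):
    """Collinear fixed-effect columns in a model design matrix."""


class NonBinaryOutcomeError(CgtcalError):
    """Probit model fitted to an outcome that is not 0/1."""


class InsufficientDrawsError(CgtcalError):
    """Too few MCMC draws for the requested posterior summary."""


class DegenerateChainsError(CgtcalError):
    """PSRF requested on chains with zero within-chain variance."""


class InvalidConfigError(CgtcalError):
    """Inconsistent cohort / pipeline configuration."""


class CorruptDataError(CgtcalError):
    """Ingested CSV data violates a task invariant (row number included)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
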