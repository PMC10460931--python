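"""Exception hierarchy shared across the validation pipeline."""


class PMValidateError(Exception):
    """Base class for all package errors."""


class MissingPredictorError(PMValidateError):
    """A model was scored on an encoding lacking one or more predictors."""

    def __init__(self, missing):
        self.missing = tuple(sorted(missing))
        super().__init__(f"missing predictors: {', '.join(self.missing)}")


class DegenerateOutcomeError(PMValidateError):
    """All outcomes identical; discrimination is undefined."""


class NonConvergenceError(PMValidateError):
    """An iteratively reweighted least squares fit failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class RankDeficiencyError(PMValidateError):
    """Design matrix is not of full column rank."""


class InsufficientDataError(PMValidateError):
    """Too little (or degenerate) data for the requested estimate."""


class EmptyCohortError(PMValidateError):
    """An operation that requires records received none."""


class CohortParseError(PMValidateError):
    """A cohort CSV violated the dialect; carries row/column context."""

    def __init__(self, message, row=None, column=None):
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + loc)
        self.row = row
        self.column = column


class AllMissingFieldError(PMValidateError):
    """A field scheduled for imputation has no observed values."""


class InfeasiblePrevalenceError(PMValidateError):
    """Requested category prevalences cannot be realised by the mixture."""


class RateInfeasibilityError(PMValidateError):
    """MAR missingness calibration could not hit the marginal rate."""


class UnknownRecordError(PMValidateError):
    """A record id was not found in the truth table."""
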