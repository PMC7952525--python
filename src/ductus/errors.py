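"""Exception hierarchy shared across the package."""


class DuctusError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(DuctusError, ValueError):
    """A numeric or categorical input violates a precondition; names the field."""


class UndefinedRatioError(DuctusError, ZeroDivisionError):
    """A ratio was requested with a zero denominator."""


class MissingMeasurementError(DuctusError, KeyError):
    """An exam lacks a measurement required by the staging scheme."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class MissingCovariateError(DuctusError, KeyError):
    """A model covariate has no value in the supplied covariate map."""

    def __str__(self) -> str:
        return self.args[0] if self.args else ""


class MissingCovarianceError(DuctusError):
    """A covariance-dependent quantity was requested from a model without one."""


class SchemeValidationError(DuctusError, ValueError):
    """A staging-scheme configuration has overlapping, gapped or unordered bins."""


class RankDeficiencyError(DuctusError):
    """The design matrix is singular; the logistic fit is not identifiable."""


class DegenerateInputError(DuctusError, ValueError):
    """An analysis needs both outcome classes (or non-degenerate data) and got one."""


class SchemaError(DuctusError, ValueError):
    """A cohort file does not match the expected CSV schema."""


class CohortFormatError(DuctusError, ValueError):
    """A cohort file cell could not be parsed; carries the offending line number."""


class ConfigError(DuctusError, ValueError):
    """A simulation configuration is infeasible (e.g. q1 > median)."""


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected during a logistic fit."""
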