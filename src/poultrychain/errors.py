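"""Exception hierarchy shared by every module.

All package errors derive from :class:`PoultryChainError` so callers can
catch the whole family with one clause; the CLI maps validation errors to
exit code 1 and configuration errors to exit code 2.
"""


class PoultryChainError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(PoultryChainError, ValueError):
    """A value is outside its physical or declared domain (NaN axis reading,
    percentage outside [0, 100], negative count, unknown category...)."""


class EmptyInputError(PoultryChainError, ValueError):
    """A KPI was requested on a series with no usable samples; the KPI is
    undefined, not zero."""


class InsufficientDataError(PoultryChainError, ValueError):
    """The input is non-empty but too short for the statistic (e.g. less
    than one full minute of accelerometer data, or a series shorter than
    the detector's lag window)."""


class ConfigurationError(PoultryChainError, ValueError):
    """Bad or inconsistent configuration: unknown formula id, comfort
    profile not covering the data span, infeasible planted fractions,
    invalid detector parameters."""


class AlignmentError(PoultryChainError, ValueError):
    """Two series that must share timestamps do not."""


class SchemaError(PoultryChainError, ValueError):
    """A tabular input is missing a required column or header."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class MissingFeatureError(PoultryChainError, KeyError):
    """A prediction needs feature values that were not supplied."""

    def __init__(self, features):
        self.features = sorted(features)
        super().__init__(
            "missing feature value(s) required to reach a decision: "
            + ", ".join(self.features)
        )
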