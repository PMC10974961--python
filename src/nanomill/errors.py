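"""Exception hierarchy for the nanomill package."""


class NanomillError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(NanomillError):
    """A file or table does not match the expected column schema."""


class TimeSeriesValidationError(NanomillError):
    """A sensor time series violates a structural invariant.

    Carries the list of :class:`nanomill.io.Violation` that triggered it.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations) or "invalid time series"
        super().__init__(msg)


class DataError(NanomillError):
    """Required data is missing or corrupted (e.g. fixture checksum mismatch)."""


class ConfigurationError(NanomillError):
    """Equipment/physical-property configuration is incomplete or inconsistent."""


class FitError(NanomillError):
    """A model fit cannot be performed on the given data."""


class BalanceError(NanomillError):
    """The energy balance is singular or cannot be evaluated."""


class SummaryError(NanomillError):
    """A batch summary cannot be computed from the run (e.g. no main segment)."""


class DesignSpaceError(NanomillError):
    """Design-space construction or surface interpolation failed."""


class ScenarioError(NanomillError):
    """A synthetic run scenario is invalid or physically unreachable."""


class ExtrapolationWarning(UserWarning):
    """A correlation is being evaluated outside its fitted range."""
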