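"""Exception hierarchy for the cbmfrax pipeline."""


class CbmError(Exception):
    """Base class for all cbmfrax errors."""


class InvalidArgumentError(CbmError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CbmError):
    """Too few observations to perform the requested estimate."""


class DegenerateProfileError(CbmError):
    """A density profile has no cortical peak to fit (constant or monotone)."""


class InvalidDesignError(CbmError):
    """A regression design matrix is rank deficient or malformed."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class MissingDataError(CbmError):
    """Required input (e.g. both hip sides) is absent."""


class EmptyPatchError(CbmError):
    """A patch with no vertices was used where values are required."""


class NotNestedError(CbmError):
    """Deviance comparison requested for non-nested model specifications."""


class InsufficientEventsError(CbmError):
    """Too few outcome events to fit a survival model."""


class UndefinedAUCError(CbmError):
    """ROC analysis requested with only one outcome class present."""


class ConfigError(CbmError):
    """A run configuration is missing or misuses a field."""

    def __init__(self, message, field=None):
        super().__init__(message)
        self.field = field
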