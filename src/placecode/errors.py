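"""Exception hierarchy shared across the pipeline."""


class PlacecodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PlacecodeError, ValueError):
    """A configuration value violates its contract (e.g. negative rate)."""


class InvalidInputError(PlacecodeError, ValueError):
    """Input data violates a precondition (non-monotone times, out-of-range positions...)."""


class UnknownTagError(PlacecodeError, KeyError):
    """An RFID event references a tag with no registered belt position."""


class FormatError(PlacecodeError, IOError):
    """A session container is unreadable or structurally corrupt."""


class SchemaVersionError(FormatError):
    """A session container was written with an incompatible schema version."""


class InsufficientTrialsError(PlacecodeError, ValueError):
    """Too few complete laps to form the trial tensor or run cross-validation."""


class SubsampleThresholdError(PlacecodeError, ValueError):
    """Fewer neurons available than the requested subsample size."""


class UndefinedActivityError(PlacecodeError, ZeroDivisionError):
    """Activity is undefined because the animal travelled zero distance."""


class UndefinedDIError(PlacecodeError, ZeroDivisionError):
    """Discrimination index undefined: no freezing in either context."""
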