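"""Exception hierarchy shared across the package."""


class ImuWristError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ImuWristError, ValueError):
    """A parameter violates a documented precondition."""


class TrialParseError(ImuWristError, ValueError):
    """A trial file could not be parsed; the message names row/column."""


class ConfigError(ImuWristError, ValueError):
    """An invalid configuration object (e.g. complementary weights h+l != 1)."""


class SampleCountError(InvalidParameterError):
    """Too few samples for the requested drift-estimation windows."""


class UndefinedTiltError(InvalidParameterError):
    """Tilt requested for a zero accelerometer vector."""


class UndefinedAUCError(InvalidParameterError):
    """ROC/AUC requested for labels containing a single class."""
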