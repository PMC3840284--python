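"""Exception hierarchy for aeforage.

Every error raised by the package derives from :class:`AEForageError`, so
callers (and the CLI) can catch one base class.
"""


class AEForageError(Exception):
    """Base class for all aeforage errors."""


class InvalidArgumentError(AEForageError, ValueError):
    """A numeric argument violates a precondition (e.g. non-positive time)."""


class InvalidBehaviorError(AEForageError):
    """An agent produced physically impossible behavior, such as a peck
    outside the circular response area."""


class StateError(AEForageError):
    """An operation was invoked in the wrong schedule state (e.g. the
    titration update called mid-block)."""


class InsufficientDataError(AEForageError, ValueError):
    """Too few sessions to evaluate a statistic (stability needs 12 session
    means, an indifference point needs 6)."""


class UndefinedStatisticError(AEForageError):
    """The requested statistic has no defined value on this log (e.g. E/RFT
    with no adjusting-energy trials at all)."""


class ConditionNotStableError(AEForageError):
    """A condition hit the hard session cap before the stability criteria
    were met.  Carries the partial session logs in ``.logs``."""

    def __init__(self, message, logs):
        super().__init__(message)
        self.logs = logs


class ConfigError(AEForageError, ValueError):
    """A configuration file violates the documented schema; the message
    names the offending key."""


class LogParseError(AEForageError, ValueError):
    """An event-log file is malformed; the message carries the line number."""


class LogVersionError(LogParseError):
    """An event-log file declares a schema version this reader does not know."""
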