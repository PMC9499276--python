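"""Exception hierarchy.

All pipeline failures derive from :class:`KneestabError` so callers can
distinguish domain errors from programming errors; per-trial failures are
caught at the pipeline level and reported without aborting the whole run.
"""


class KneestabError(Exception):
    """Base class for all kneestab domain errors."""


class InvalidConfigError(KneestabError, ValueError):
    """A configuration value violates its physical or logical range."""


class SchemaError(KneestabError, ValueError):
    """An input file does not match the expected column schema."""


class TooShortWindowError(KneestabError, ValueError):
    """A window is shorter than the minimum the operation requires."""


class WrongSensorError(KneestabError, ValueError):
    """An operation received a recording from the wrong sensor location."""


class InitializationError(KneestabError, RuntimeError):
    """Orientation initialisation failed (e.g. non-gravitational start)."""


class NoMovementError(KneestabError, RuntimeError):
    """No movement onset satisfied the start rule."""


class UnterminatedTaskError(KneestabError, RuntimeError):
    """The signal never returned to its initial value."""


class UnbalancedEventsError(KneestabError, RuntimeError):
    """Take-off and landing counts differ."""

    def __init__(self, msg, takeoffs=None, landings=None):
        super().__init__(msg)
        self.takeoffs = list(takeoffs) if takeoffs is not None else []
        self.landings = list(landings) if landings is not None else []


class InsufficientHopsError(KneestabError, RuntimeError):
    """Fewer complete hops than the feature definitions require."""


class NoFlightError(KneestabError, RuntimeError):
    """Vertical ground reaction force never reached the flight threshold."""


class DegenerateEllipseError(KneestabError, RuntimeError):
    """Point cloud covariance is rank deficient; eccentricity is 1."""

    def __init__(self, msg, ecc=1.0):
        super().__init__(msg)
        self.ecc = ecc


class UndefinedIccError(KneestabError, ValueError):
    """ICC is undefined (zero total variance)."""


class UndefinedLsiError(KneestabError, ZeroDivisionError):
    """LSI is undefined (dominant-limb value is zero)."""


class EmptyInputError(KneestabError, ValueError):
    """A manifest or window contained no usable data."""
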