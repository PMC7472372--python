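"""Exception hierarchy shared across fixmon modules."""


class FixmonError(Exception):
    """Base class for all fixmon-specific errors."""


class BlockSizeError(FixmonError, ValueError):
    """A telemetry block does not contain exactly the required frame count."""


class CountRangeError(FixmonError, ValueError):
    """An ADC count falls outside the signed 16-bit range."""


class InsufficientDataError(FixmonError, ValueError):
    """An operation received fewer samples/rows than it needs."""


class NoStanceError(FixmonError, ValueError):
    """A ground-reaction-force trace contains no detectable stance phase."""


class DegenerateStepError(FixmonError, ValueError):
    """Fixator load share at the stance peak is below the division guard.

    Signals a callus consolidated beyond the measurable range rather than a
    data defect; callers may treat it as a warning.
    """


class ProtocolError(FixmonError, ValueError):
    """A requested time-point lies outside the clinical protocol phase."""


class DomainError(FixmonError, ValueError):
    """A parameter violates its mathematical domain (e.g. non-positive Ksr)."""


class ConfigError(FixmonError, ValueError):
    """A pipeline/session configuration is incomplete or inconsistent."""
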