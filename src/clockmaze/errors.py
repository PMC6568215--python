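"""Exception hierarchy for the clockmaze package."""


class ClockmazeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClockmazeError):
    """An arena or run configuration violates one of its constraints."""


class FormatError(ClockmazeError):
    """A delimited input file is malformed (bad header, bad row, bad time axis)."""


class ValidationError(ClockmazeError):
    """Input values violate an operation's preconditions."""


class CapabilityError(ClockmazeError):
    """The requested computation needs data the (degraded) track does not carry."""


class MalformedTrialError(ClockmazeError):
    """A track ends before the cutoff without satisfying the escape rule."""


class UnsupportedVariantError(ClockmazeError):
    """The operation is undefined for this arena variant."""
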