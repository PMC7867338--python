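"""Exception hierarchy shared across the pipeline."""


class SensomeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(SensomeError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(SensomeError):
    """Input data violates a structural invariant."""


class ParseError(SensomeError):
    """A file could not be parsed; the message locates the offending cell."""


class QCError(SensomeError):
    """Sample quality control left the analysis undefined."""
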