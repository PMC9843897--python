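"""Exception hierarchy shared across the pipeline.

The split mirrors the failure classes callers care about: a *format* error
means the bytes on disk are not the advertised format, a *validation* error
means the format parsed but the content violates an invariant, and a
*configuration* error means the caller wired the stages together wrongly.
"""


class ConvexprError(Exception):
    """Base class for all package errors."""


class FormatError(ConvexprError):
    """The input file does not conform to the expected on-disk format."""


class ValidationError(ConvexprError):
    """Parsed content violates a domain invariant."""


class ConfigurationError(ConvexprError):
    """Stages or parameters are wired together inconsistently."""
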