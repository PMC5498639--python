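"""Exception hierarchy shared across the pipeline."""


class OccupetError(Exception):
    """Base class for all package errors."""


class FormatError(OccupetError):
    """A file violates the documented CSV dialect or a type invariant."""


class ConfigError(OccupetError):
    """Study configuration is inconsistent (duplicate subjects, bad labels...)."""


class DomainError(OccupetError, ValueError):
    """A quantity is outside its physical domain (negative dose, Vb >= 1...)."""


class InsufficientDataError(OccupetError):
    """Too few samples/frames to perform the requested fit."""
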