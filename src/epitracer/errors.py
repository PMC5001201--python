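"""Exception hierarchy.

Every error raised by this package derives from :class:`EpitracerError`
so that callers (and the CLI) can catch one type at the pipeline boundary.
"""


class EpitracerError(Exception):
    """Base class for all errors raised by epitracer."""


class ParseError(EpitracerError):
    """An input file could not be parsed; the message names the line."""


class DomainError(EpitracerError):
    """A value lies outside the mathematical domain of an operation
    (e.g. a non-positive signal intensity fed to the edge-cost formula)."""


class ParameterError(EpitracerError):
    """A user-supplied parameter is out of range (percentile, cutoff, ...)."""


class ConfigurationError(EpitracerError):
    """Two pipeline stages were combined with inconsistent settings."""


class IntegrityError(EpitracerError):
    """An internal consistency check failed (e.g. a path references an
    edge absent from its network)."""
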