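"""Exception hierarchy.

All errors raised by hicdci derive from :class:`HicDciError` so callers
(and the CLI) can catch package failures with a single except clause.
"""


class HicDciError(Exception):
    """Base class for all hicdci errors."""


class FormatError(HicDciError):
    """A file does not conform to its declared dialect."""


class ValidationError(HicDciError):
    """An in-memory object violates a structural invariant."""


class ConfigurationError(HicDciError):
    """Mutually inconsistent or unsupported parameters."""
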