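"""Exception hierarchy for spliceid.

All domain errors derive from :class:`SpliceIdError` so callers (and the
CLI) can distinguish them from programming errors.
"""


class SpliceIdError(Exception):
    """Base class for all spliceid domain errors."""


class ValidationError(SpliceIdError):
    """Input violates a documented invariant (duplicate ids, bad labels...)."""


class ParseError(SpliceIdError):
    """A file does not conform to its declared format."""


class EncodingError(SpliceIdError):
    """A record cannot be encoded by the requested feature block."""


class EmptyDatasetError(SpliceIdError):
    """An operation received an empty dataset where records are required."""
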