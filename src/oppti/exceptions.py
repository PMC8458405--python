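"""Exception hierarchy shared across the package."""


class OpptiError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OpptiError):
    """A file could not be parsed (malformed header, bad cell, duplicate ID)."""


class DataError(OpptiError):
    """Input data violate a precondition of an operation."""
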