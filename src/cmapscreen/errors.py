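"""Exception hierarchy shared across the package."""


class CmapScreenError(Exception):
    """Base class for all package errors."""


class FormatError(CmapScreenError, ValueError):
    """A file does not conform to its declared dialect (bad header, wrong
    dimensions, unknown format name)."""


class ParseError(FormatError):
    """A cell could not be parsed; the message carries row/column coordinates."""


class ValidationError(CmapScreenError, ValueError):
    """A domain invariant is violated (duplicate ids, empty intersection,
    group too small, non-permutation profile, ...)."""


class DomainError(ValidationError):
    """A numeric precondition is violated (non-positive value before log2,
    non-finite expression value)."""
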