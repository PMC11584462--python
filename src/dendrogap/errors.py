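"""Exception hierarchy shared across the package."""


class DendrogapError(Exception):
    """Base class for all package errors."""


class FormatError(DendrogapError):
    """A file could not be parsed into the declared CSV dialect."""


class IntegrityError(DendrogapError):
    """Input data violates a structural contract (duplicates, off-grid rows)."""


class GridError(DendrogapError):
    """A series does not sit on a regular time grid."""


class EmptyOverlapError(DendrogapError):
    """Two series share no common grid span."""


class InsufficientDataError(DendrogapError):
    """Too few non-missing points for the requested operation."""


class SpecError(DendrogapError):
    """Invalid simulation or configuration parameters."""
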