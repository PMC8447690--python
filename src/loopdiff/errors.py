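"""Exception hierarchy shared across the pipeline."""


class LoopdiffError(Exception):
    """Base class for all package errors."""


class MalformedInputError(LoopdiffError):
    """An input file violates its expected dialect (names the offending line)."""


class LayoutError(LoopdiffError):
    """Genome layouts are inconsistent (bin widths, chromosome mismatch)."""


class ValidationError(LoopdiffError):
    """A parsed record violates a domain invariant."""


class ParameterError(LoopdiffError):
    """A user-supplied parameter is out of range."""


class InsufficientDataError(LoopdiffError):
    """Too little data to perform the requested fit."""


class DegenerateInputError(LoopdiffError):
    """The input admits no non-trivial answer (e.g. zero variance)."""
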