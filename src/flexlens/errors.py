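"""Exception hierarchy.

All flexlens errors derive from :class:`FlexLensError` so callers can catch
one base class; the subclasses mirror the failure categories the library
reports (malformed files, bad parameters, invalid in-memory input, and
degenerate superposition problems).
"""


class FlexLensError(Exception):
    """Base class for all flexlens errors."""


class FormatError(FlexLensError, ValueError):
    """A file does not conform to the dialect a reader expects."""


class ParameterError(FlexLensError, ValueError):
    """A function parameter is outside its documented domain."""


class InputError(FlexLensError, ValueError):
    """In-memory input violates a precondition (lengths, alphabets, ...)."""


class AlignmentError(FlexLensError, ValueError):
    """Rigid-body superposition is undefined for the given coordinates."""
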