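"""Exception hierarchy.

All package errors derive from :class:`VppgrfError` so callers can catch the
whole family; validation and parse errors additionally derive from
``ValueError`` to behave naturally in generic code.
"""


class VppgrfError(Exception):
    """Base class for all vppgrf errors."""


class ValidationError(VppgrfError, ValueError):
    """Invalid values or inconsistent inputs (bad parameters, length mismatch)."""


class ParseError(VppgrfError, ValueError):
    """Malformed input file; the message names the offending row/column."""


class SegmentationError(VppgrfError, RuntimeError):
    """No qualifying movement segment was found in the trial."""


class IllConditionedError(VppgrfError, RuntimeError):
    """The two virtual pivot vectors are (numerically) parallel."""


class DegenerateFrameError(VppgrfError, RuntimeError):
    """A per-frame geometric quantity is undefined (e.g. vanishing vertical force)."""
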