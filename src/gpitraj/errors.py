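"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`GpitrajError`
so callers (and the CLI) can distinguish analysis failures from bugs.
"""


class GpitrajError(Exception):
    """Base class for all package errors."""


class ParseError(GpitrajError):
    """A structure file could not be parsed (message names the offending line)."""


class StructureError(GpitrajError):
    """Structurally inconsistent input (atom-count mismatch across models, etc.)."""


class SelectionError(GpitrajError):
    """Selection expression is syntactically invalid or resolves unexpectedly."""


class SpecError(GpitrajError):
    """A synthetic-data specification violates its own invariants."""


class DegenerateBodyError(GpitrajError):
    """Point set too degenerate for superposition (collinear, < 3 points, ...)."""


class AnalysisError(GpitrajError):
    """An analysis precondition failed (empty trajectory, single frame, ...)."""
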