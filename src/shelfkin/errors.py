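"""Exception hierarchy for shelfkin.

All package errors derive from :class:`ShelfKinError` so callers can catch
one base class; subclasses distinguish parse problems, insufficient or
degenerate data, and domain violations (e.g. non-positive values passed to a
log-scale fit).
"""


class ShelfKinError(Exception):
    """Base class for all shelfkin errors."""


class ParseError(ShelfKinError, ValueError):
    """Malformed input text or CSV row; message names the offending line."""


class DuplicationError(ShelfKinError, ValueError):
    """Two rows claim the same (attribute, condition, week) slot."""


class FixtureLookupError(ShelfKinError, KeyError):
    """Unknown built-in fixture or missing series requested."""


class InsufficientDataError(ShelfKinError, ValueError):
    """Fewer observations than the operation's minimum."""


class DegenerateDesignError(ShelfKinError, ValueError):
    """Regression design has no usable variation (e.g. one distinct time)."""


class DomainError(ShelfKinError, ValueError):
    """A value lies outside the mathematical domain of the operation."""


class ConsistencyError(ShelfKinError, ValueError):
    """Objects that must share provenance do not."""
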