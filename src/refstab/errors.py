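"""Exception hierarchy for refstab.

All refstab-raised errors derive from :class:`RefstabError` so callers can
catch the whole family with one clause.
"""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError):
    """A file could not be parsed (missing column, bad literal, ...)."""


class ValidationError(RefstabError):
    """Parsed data violate a structural invariant (duplicates, empty sets, ...)."""


class InsufficientDataError(RefstabError):
    """Not enough observations for the requested computation."""


class DomainError(RefstabError):
    """An input is outside the mathematical domain of the operation."""


class SingularFitError(RefstabError):
    """A regression design matrix is singular (e.g. zero spread in x)."""


class GroupingError(RefstabError):
    """Sample group structure is unusable (e.g. a group is too small)."""
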