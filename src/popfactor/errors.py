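"""Typed exceptions.

Undefined scores (0/0 ratios, degenerate subspaces) raise rather than
returning sentinel values, so downstream meta-analysis tables can never
silently absorb a meaningless number.
"""


class PopfactorError(Exception):
    """Base class for all package errors."""


class FormatError(PopfactorError):
    """A file or in-memory container violates the expected layout."""


class DesignError(PopfactorError):
    """An augmentation/grouping design table violates its invariants."""


class VocabularyError(DesignError):
    """A scene-parameter name outside the supported vocabulary."""


class AlignmentError(PopfactorError):
    """Two containers that must share conditions do not line up."""


class UndefinedScoreError(PopfactorError):
    """A metric is mathematically undefined for this input (e.g. 0/0)."""


class DegenerateSubspaceError(UndefinedScoreError):
    """A principal subspace has rank zero."""


class RankError(PopfactorError):
    """Not enough independent directions to carry out an operation."""


class StratificationError(PopfactorError):
    """Cross-validation folds cannot be stratified for these labels."""
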