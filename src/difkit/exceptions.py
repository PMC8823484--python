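"""Exception hierarchy for difkit.

All package errors derive from :class:`DifkitError` so callers can catch one
type at pipeline boundaries while tests discriminate the specific failure.
"""


class DifkitError(Exception):
    """Base class for all difkit errors."""


class SchemaError(DifkitError):
    """Input table does not match the expected schema (columns, ids)."""


class ParseError(DifkitError):
    """A cell value could not be interpreted under the configured coding."""


class StateError(DifkitError):
    """Operation called on an object in the wrong state (e.g. unscored matrix)."""


class DegenerateItemError(DifkitError):
    """An item has only one observed response category and cannot be calibrated."""

    def __init__(self, item_ids):
        self.item_ids = list(item_ids)
        super().__init__(
            f"items with a single observed response category: {self.item_ids}"
        )


class NoAnchorError(DifkitError):
    """Every item is flagged for DIF, leaving no anchor to link the trait metric."""


class InsufficientDataError(DifkitError):
    """A group level has too few persons for a stable calibration."""


class SeparationError(DifkitError):
    """Quasi-complete separation: the logistic ML estimate diverges."""

    def __init__(self, column, message=None):
        self.column = column
        super().__init__(
            message or f"quasi-complete separation detected on design column {column}"
        )


class DesignError(DifkitError):
    """Rank-deficient or otherwise invalid design matrix."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at its iteration cap without converging."""
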