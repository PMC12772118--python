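"""Exception hierarchy.

Every stage raises a dedicated subclass of :class:`PanelexError` so that
callers (and the CLI) can report which stage failed.
"""


class PanelexError(Exception):
    """Base class for all panelex errors."""


class TableFormatError(PanelexError):
    """Malformed quantity table: duplicate names, non-numeric cells, ..."""


class GroupingError(PanelexError):
    """Sample columns cannot be grouped into conditions."""


class PreprocessingError(PanelexError):
    """Normalization or sparsity filtering failed."""


class SplitError(PanelexError):
    """Train/test split would empty a condition."""


class FitError(PanelexError):
    """d-LDA model cannot be fitted."""


class PredictionError(PanelexError):
    """Features of the query matrix do not match the fitted model."""


class CVError(PanelexError):
    """Cross-validation configuration infeasible for the data."""


class FilterError(PanelexError):
    """p-value filter retained no molecules."""


class WrapperError(PanelexError):
    """Wrapper repetition could not run."""


class EvaluationError(PanelexError):
    """Final panel evaluation failed."""
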