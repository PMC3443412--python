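"""Exception hierarchy for snslink.

All library errors derive from :class:`SnsLinkError` so callers can catch the
package's failures with a single except clause while still distinguishing
parse, validation, calibration and sampling problems.
"""


class SnsLinkError(Exception):
    """Base class for all snslink errors."""


class EdgeListParseError(SnsLinkError):
    """A TSV edge-list row could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class GraphValidationError(SnsLinkError):
    """Graph-level invariant violated (forbidden category, self-loop, ...)."""


class NodeLookupError(SnsLinkError, KeyError):
    """A node id was not found in the graph."""


class UnsupportedCategoryError(SnsLinkError):
    """Operation asked for a link category it does not support."""


class CalibrationFitError(SnsLinkError):
    """Logistic fit impossible (too few points, no positive class, ...)."""


class MonotonicityError(CalibrationFitError):
    """Fit converged to a non-increasing connecting-probability curve (b >= 0)."""


class CalibrationMissingError(SnsLinkError):
    """Extended scoring requested a category with no calibrated probabilities."""


class InsufficientDataError(SnsLinkError):
    """Not enough pairs/edges for the requested statistic."""


class SampleSizeError(SnsLinkError):
    """Requested sample exceeds the available population."""


class DegenerateLabelsError(SnsLinkError):
    """ROC requested on single-class labels."""
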