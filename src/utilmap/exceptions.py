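"""Exception taxonomy.

Errors are grouped so callers (and the CLI exit-status mapping) can
distinguish bad input labels, missing data, malformed files, degenerate
estimation problems and prediction-time schema mismatches.
"""


class UtilmapError(Exception):
    """Base class for all package errors."""


class EncodingError(UtilmapError, ValueError):
    """An item response label could not be mapped to an ordinal level."""


class MissingItemsError(UtilmapError, ValueError):
    """Required questionnaire items are missing; lists the offending items."""

    def __init__(self, items, message=None):
        self.items = tuple(items)
        super().__init__(message or f"missing required QoL-AD items: {list(self.items)}")


class StateError(UtilmapError, ValueError):
    """An EQ-5D health-state profile is malformed for its version."""


class FormatError(UtilmapError, ValueError):
    """A CSV input does not conform to the documented schema."""


class CrosswalkIntegrityError(FormatError):
    """A crosswalk table fails validation (row count, duplicates, range)."""


class EmptyScenarioError(UtilmapError, ValueError):
    """Complete-case filtering left zero usable rows for a scenario."""


class SingularDesignError(UtilmapError, ValueError):
    """Design matrix is rank deficient; names the aliased columns."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"rank-deficient design; aliased columns: {self.aliased}")


class DegenerateDataError(UtilmapError, ValueError):
    """The outcome configuration cannot identify the requested model."""


class PredictionError(UtilmapError, ValueError):
    """New data cannot be encoded under the fitted covariate specification."""


class DistributionError(UtilmapError, ValueError):
    """A predicted level distribution is invalid (negative / not summing to 1)."""


class DegenerateClusterError(UtilmapError, ValueError):
    """Fewer than two clusters supplied to the cluster-robust estimator."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at its iteration cap; last iterate retained."""
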