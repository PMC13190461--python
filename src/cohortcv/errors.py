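"""Exception hierarchy shared across the package."""


class CohortCVError(Exception):
    """Base class for all package errors."""


class ParseError(CohortCVError):
    """A file cell could not be parsed; message names the row and column."""


class CohortValidationError(CohortCVError):
    """One or more cohort invariants are violated.

    ``violations`` holds the individual human-readable descriptions.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ParameterError(CohortCVError):
    """Infeasible or out-of-range parameter values."""


class EmptyTableError(CohortCVError):
    """A filter removed every taxon (or every sample)."""


class StateError(CohortCVError):
    """An operation was applied before its fit state existed."""


class StratificationError(CohortCVError):
    """A class is too small for the requested number of folds."""


class MetricsUndefinedError(CohortCVError):
    """Discrimination metrics requested on a single-class label set."""


class FitError(CohortCVError):
    """A model fit failed (e.g. single-class training labels)."""
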