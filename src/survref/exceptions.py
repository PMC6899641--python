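"""Exception hierarchy.

Distinct classes so callers (and the CLI exit-code mapping) can tell data
validation problems apart from numerical failures.
"""


class SurvrefError(Exception):
    """Base class for all package errors."""


class ValidationError(SurvrefError, ValueError):
    """Input data violate a dataset invariant (bad time/event/arm, duplicate ids...)."""


class SpecificationError(SurvrefError, ValueError):
    """An analysis was mis-specified (missing delta, K too small, grid mismatch...)."""


class DegenerateDataError(SurvrefError, ValueError):
    """Data cannot identify the model (e.g. an arm with no observed events)."""


class ConvergenceError(SurvrefError, RuntimeError):
    """Likelihood maximisation failed to converge within the iteration budget."""

    def __init__(self, message: str, context: str | None = None):
        if context:
            message = f"{message} [context: {context}]"
        super().__init__(message)
        self.context = context


class MatrixError(SurvrefError, ValueError):
    """A covariance matrix is not positive semi-definite after symmetrisation/clipping."""
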