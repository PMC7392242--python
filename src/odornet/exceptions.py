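"""Exception hierarchy shared across the package.

Validation/schema errors indicate bad user input; numerical errors indicate a
failure of an estimation routine on otherwise valid input. The CLI maps the two
branches to distinct exit codes.
"""


class OdornetError(Exception):
    """Base class for all package errors."""


class ValidationError(OdornetError):
    """A value violates its documented scale range or invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or is otherwise malformed."""


class IntegrityError(OdornetError):
    """A packaged fixture failed its integrity checks on load."""


class ClassificationError(OdornetError):
    """An odor cannot be classified as pleasant or unpleasant (tied mean)."""


class ConstructionError(OdornetError):
    """A target precision matrix is not positive definite."""


class NumericalError(OdornetError):
    """Base class for estimation-stage failures."""


class ConvergenceError(NumericalError):
    """An iterative solver failed to converge within its iteration budget."""


class EstimationError(NumericalError):
    """A network could not be estimated from the given data."""
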