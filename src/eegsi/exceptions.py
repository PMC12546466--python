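"""Exception hierarchy for eegsi.

All errors derive from :class:`EegsiError` so callers can catch the whole
family; most also derive from the closest builtin (ValueError / RuntimeError)
so that generic handling keeps working.
"""


class EegsiError(Exception):
    """Base class for all eegsi errors."""


class GeometryError(EegsiError, ValueError):
    """Invalid source/electrode geometry (e.g. source outside the brain shell)."""


class ModelError(EegsiError, ValueError):
    """Invalid head-model specification (e.g. non-ascending shell radii)."""


class FormatError(EegsiError, ValueError):
    """A file does not parse under the declared on-disk format."""


class DegenerateMeasurementError(EegsiError, ValueError):
    """Simulated measurement would be identically zero with zero noise."""


class DegenerateLocationError(EegsiError, ValueError):
    """A sub-lead-field is identically zero; no orientation basis exists."""

    def __init__(self, location: int, message: str | None = None):
        self.location = location
        super().__init__(message or f"sub-lead-field at location {location} is degenerate")


class ProvenanceError(EegsiError, ValueError):
    """An object is used with data it was not built from."""


class CovarianceError(EegsiError, ValueError):
    """A covariance matrix is not symmetric positive definite."""


class RankError(EegsiError, ValueError):
    """A sub-lead-field is rank deficient where full rank is required."""


class SilentSourceError(EegsiError, ValueError):
    """The oriented source produces no signal (L_k theta = 0)."""


class UndefinedFitError(EegsiError, ValueError):
    """Goodness of fit is undefined (zero measurement vector)."""


class NoSourceError(EegsiError, RuntimeError):
    """An estimator returned an all-zero field where a source is required."""


class InfeasibleSelectionError(EegsiError, RuntimeError):
    """Hyperparameter selection has no feasible solution (e.g. zero data)."""


class SchemaError(EegsiError, ValueError):
    """A run configuration fails schema validation."""
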