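"""Exception taxonomy for the pipeline.

Validation problems (bad configuration, malformed inputs) raise
:class:`ConfigurationError` subclasses; runtime/numerical failures raise
:class:`PmetError` subclasses so callers can distinguish the two.
"""


class PmetError(Exception):
    """Base class for runtime errors raised by pmet."""


class ConfigurationError(PmetError):
    """Invalid configuration or malformed input data."""


class DesignError(PmetError):
    """The requested statistical design cannot be built from the data."""


class ReferencingError(PmetError):
    """Chemical-shift referencing failed (no usable doublet in the window)."""


class NormalizationError(PmetError):
    """Total-area normalisation is undefined (non-positive retained area)."""


class IntegrationError(PmetError):
    """A requested integration window lies outside the spectral axis."""


class ImputationError(PmetError):
    """Below-LOD imputation requested for a variable without a defined LOD."""


class FitError(PmetError):
    """Model fitting failed (e.g. residual rank exhausted)."""


class PredictionError(PmetError):
    """Prediction inputs are incompatible with the fitted model."""


class ConvergenceError(PmetError):
    """An iterative model fit did not converge to a usable solution."""
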