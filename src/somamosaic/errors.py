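"""Exception hierarchy shared across the pipeline stages."""


class SomamosaicError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SomamosaicError, ValueError):
    """A parameter violates a documented precondition."""


class InvalidInputError(SomamosaicError, ValueError):
    """Input data violate a documented precondition."""


class ConfigurationError(SomamosaicError, ValueError):
    """A required configuration entry (error-rate class, frequency) is missing or invalid."""


class InsufficientPanelError(SomamosaicError, ValueError):
    """Fewer than two usable panel-of-normals samples at a site."""


class CalibrationError(SomamosaicError, ValueError):
    """ROC calibration needs at least one true and one false label."""


class FitError(SomamosaicError, ValueError):
    """A regression fit is degenerate (too few points, no age spread)."""


class AnnotationError(SomamosaicError, ValueError):
    """Variant annotations required for a filter are missing."""


class ReferentialIntegrityError(SomamosaicError, ValueError):
    """A call references a subject or tissue absent from the metadata table."""


class BudgetError(SomamosaicError, ValueError):
    """A combinatorial search would exceed its configured budget."""
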