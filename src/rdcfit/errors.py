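"""Exception hierarchy used across the package."""


class RdcFitError(Exception):
    """Base class for all rdcfit errors."""


class FormatError(RdcFitError):
    """A coordinate or RDC file could not be parsed."""


class EmptySelectionError(RdcFitError):
    """A filter or intersection left nothing to work with."""


class UnderDeterminedError(RdcFitError):
    """Fewer usable records than free parameters (5 for a full Saupe tensor)."""


class DegenerateGeometryError(RdcFitError):
    """Geometrically rank-deficient input (e.g. collinear superposition atoms)."""


class UndefinedNormalizationError(RdcFitError):
    """Q-factor normalization undefined (alignment strength Da is zero)."""


class IllConditionedWarning(UserWarning):
    """Design matrix condition number above the configured threshold."""
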