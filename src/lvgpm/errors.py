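"""Exception hierarchy for the lvgpm pipeline.

Exit-code mapping used by the CLI: ValidationError-family -> 2,
ComputationError-family -> 3.
"""


class LvgpmError(Exception):
    """Base class for all package errors."""


class ValidationError(LvgpmError):
    """Invalid inputs, configs or study files."""


class DegenerateGeometryError(ValidationError):
    """Collinear/duplicate points or otherwise degenerate geometric input."""


class ConfigurationError(ValidationError):
    """Inconsistent acquisition or pipeline configuration."""


class InsufficientSlicesError(ValidationError):
    """A slice-reduction protocol was asked for more slices than exist."""


class PairingError(ValidationError):
    """Paired-statistics input vectors do not line up."""


class SchemaError(ValidationError):
    """Study file does not validate against the published schema."""


class ComputationError(LvgpmError):
    """A numerical stage failed."""


class GeometryError(ComputationError):
    """Plane/surface intersection or volume integration failed."""


class ContourTopologyError(ComputationError):
    """Self-intersecting or otherwise unusable contour."""


class UnderdeterminedFitError(ComputationError):
    """Not enough data points to determine the surface coefficients."""

    def __init__(self, frame: int, detail: str = ""):
        self.frame = frame
        super().__init__(f"surface fit under-determined at frame {frame}" +
                         (f": {detail}" if detail else ""))
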