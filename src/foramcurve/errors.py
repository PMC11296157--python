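"""Exception hierarchy shared across the package."""


class ForamcurveError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(ForamcurveError):
    """Grey/label grids (or two segmentations) disagree in shape."""


class LabelError(ForamcurveError):
    """A label grid contains codes outside the convention."""


class GeometryError(ForamcurveError):
    """Requested geometry cannot be realised (phantom does not fit,
    volume smaller than a patch, degenerate mesh, ...)."""


class SpecificationError(ForamcurveError):
    """Inconsistent user-supplied configuration."""


class EvaluationError(ForamcurveError):
    """A metric is undefined for the given inputs."""


class TrainingError(ForamcurveError):
    """Network training failed."""
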