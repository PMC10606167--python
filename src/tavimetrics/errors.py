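"""Exception hierarchy shared across the pipeline.

Every stage failure derives from :class:`TavimetricsError` so callers (and
the CLI exit-code mapping) can distinguish input/validation problems from
geometric failures inside a pipeline stage.
"""


class TavimetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(TavimetricsError):
    """Input fails a documented invariant (bad mesh, collinear nadirs, ...)."""


class FormatError(ValidationError):
    """A file could not be parsed in the declared format."""


class SchemaError(ValidationError):
    """A structured file is missing required keys or has the wrong shape."""


class GeometryError(TavimetricsError):
    """A geometric construction failed (empty section, degenerate plane, ...)."""


class EmptySectionError(GeometryError):
    """Plane does not intersect the mesh in any closed loop."""


class DegenerateSectionError(GeometryError):
    """All intersection loops are degenerate (area below threshold)."""


class ConvergenceError(TavimetricsError):
    """An iterative procedure failed to converge; carries diagnostics."""

    def __init__(self, message: str, iterations: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class TopologyError(TavimetricsError):
    """A skeleton/centerline has topology that cannot be reduced to a path."""


class StageError(TavimetricsError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
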