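"""Exception hierarchy for the well-TFM pipeline."""


class WellTfmError(Exception):
    """Base class for all pipeline errors."""


class AmbiguousSurfaceError(WellTfmError):
    """No unique intensity peak identifies the gel top surface."""


class DetectionFailureError(WellTfmError):
    """Automatic well-circumference detection found no acceptable circle."""


class ConfigError(WellTfmError):
    """Invalid configuration value or block."""


class MeshingError(WellTfmError):
    """Mesh generation failed for the requested geometry."""


class SolverError(WellTfmError):
    """FEM or inverse solver failed to produce a valid solution."""


class CoverageError(WellTfmError):
    """Interpolation data does not cover the requested points."""


class UndefinedMetricError(WellTfmError):
    """A summary metric is undefined for the given input (e.g. CoV at zero mean)."""
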