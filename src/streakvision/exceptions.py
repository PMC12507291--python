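"""Exception hierarchy for streakvision."""


class StreakVisionError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StreakVisionError, ValueError):
    """A numeric argument is outside its valid domain."""


class SchedulingError(StreakVisionError, ValueError):
    """A target-motion schedule does not fit inside the saccade."""


class RenderError(StreakVisionError, ValueError):
    """The stimulus leaves the retinotopic canvas during rendering."""


class ConfigurationError(StreakVisionError, ValueError):
    """Inconsistent model configuration (pitch/rate/kernel mismatches)."""


class FitError(StreakVisionError, RuntimeError):
    """An optimisation or smoothing step failed."""


class SchemaError(StreakVisionError, ValueError):
    """An HDF5 container does not match the expected schema."""
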