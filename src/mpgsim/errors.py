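"""Exception types raised by the simulator."""


class MPGError(Exception):
    """Base class for all mpgsim errors."""


class ConfigError(MPGError):
    """Invalid or inconsistent configuration value."""


class UnitsError(MPGError):
    """Physically meaningless quantity (non-positive energy, distance, ...)."""


class SamplingError(MPGError):
    """Grid too coarse to resolve the structure being sampled or propagated."""


class CoverageError(MPGError):
    """Grid or detector window too narrow for the requested analysis."""


class UndefinedVisibilityError(MPGError):
    """Visibility requested on an identically-zero intensity profile."""


class DemodulationError(MPGError):
    """No detectable fringe carrier at the expected spatial frequency."""


class InfeasibleDesignError(MPGError):
    """Source-grating design constraint cannot be met (open ratio >= 1)."""
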