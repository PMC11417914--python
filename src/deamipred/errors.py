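"""Exception hierarchy shared across the package."""


class DeamipredError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DeamipredError, ValueError):
    """Input violates a domain invariant (alphabet, range, residue identity...)."""


class ParseError(DeamipredError, ValueError):
    """A file could not be parsed into domain records."""


class ConfigError(DeamipredError, ValueError):
    """Invalid run configuration."""


class CapacityError(DeamipredError, ValueError):
    """Input exceeds a backend's maximum supported size."""


class ShapeError(DeamipredError, ValueError):
    """Array/feature dimensions do not match what a model expects."""


class TrainingError(DeamipredError, RuntimeError):
    """Training cannot proceed (e.g. single-class split)."""


class GenerationError(DeamipredError, RuntimeError):
    """Synthetic data generation failed its own calibration checks."""
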