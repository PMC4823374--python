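"""Exception hierarchy shared across the pipeline stages."""


class VemsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(VemsegError, ValueError):
    """Non-positive or mismatched voxel dimensions."""


class FormatError(VemsegError, ValueError):
    """Unreadable or inconsistent image/label files."""


class TrainingError(VemsegError, ValueError):
    """Training data insufficient for the Gaussian model."""


class InfeasibleEnergyError(VemsegError, RuntimeError):
    """The minimizer could not avoid a forbidden (INF) label adjacency."""


class GenerationError(VemsegError, RuntimeError):
    """Phantom objects could not be placed without overlap."""
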