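"""Exception hierarchy for neurongrowth."""


class NeuronGrowthError(Exception):
    """Base class for all package errors."""


class InvalidSplineSpaceError(NeuronGrowthError):
    """Requested B-spline space cannot be constructed (e.g. n < p + 1)."""


class OutOfDomainError(NeuronGrowthError):
    """Evaluation point lies outside the knot span."""


class AssemblyError(NeuronGrowthError):
    """Collocation operator assembly produced a singular system."""


class DimensionError(NeuronGrowthError):
    """Field shape does not match the collocation lattice."""


class ConfigurationError(NeuronGrowthError):
    """Invalid model configuration (overlapping cells, bad parameters...)."""


class ParameterError(NeuronGrowthError):
    """A model coefficient is outside its admissible range."""


class InitializationError(NeuronGrowthError):
    """State initialization failed (e.g. no initial interface)."""


class NumericalBlowupError(NeuronGrowthError):
    """Non-finite values encountered during time stepping."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class NonConvergenceError(NeuronGrowthError):
    """Newton iteration failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None,
                 iteration: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iteration = iteration


class EmptyStateError(NeuronGrowthError):
    """No connected component above threshold in the phase field."""


class DisconnectedTipError(NeuronGrowthError):
    """Tip is not connected to the soma within the phi > threshold mask."""


class SelectionError(NeuronGrowthError):
    """Axon selection requested on an empty tip set."""


class InsufficientLengthError(NeuronGrowthError):
    """Trace too short for the requested change-point window q."""
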