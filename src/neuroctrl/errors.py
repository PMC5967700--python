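"""Exception types shared across the package."""


class NeuroctrlError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NeuroctrlError):
    """Invalid input data or configuration (bad matrix, bad spec, bad config)."""


class IntegrationError(NeuroctrlError):
    """The ODE integrator produced a non-finite state.

    Attributes
    ----------
    step : int
        Index of the step at which the state stopped being finite.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ControllabilityError(NeuroctrlError):
    """The pointwise Riccati problem has no acceptable stabilizing solution.

    Carries the input node and, when raised during a simulation, the index of
    the gain-update instant at which the failure occurred.
    """

    def __init__(self, message: str, input_node: int | None = None,
                 time_index: int | None = None):
        super().__init__(message)
        self.input_node = input_node
        self.time_index = time_index


class CalibrationError(NeuroctrlError):
    """Root bracketing for the stiffness calibration failed."""


class UndefinedFrequencyError(NeuroctrlError):
    """Spectral peak is undefined (constant or degenerate signal)."""
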