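"""Exception hierarchy for the vv-ECMO gas exchange model."""


class VvecmoError(Exception):
    """Base class for all model errors."""


class DomainError(VvecmoError, ValueError):
    """An input is outside the physical/physiological domain."""


class InfeasibleContentError(VvecmoError):
    """A blood-gas content triple cannot be produced by any tension."""


class DegenerateMixError(VvecmoError):
    """Attempted to mix blood streams whose flows are all zero."""


class UntenableStateError(VvecmoError):
    """The requested steady state would need negative mixed-venous O2
    content (or an equivalently unphysical intermediate); the scenario
    has no physiological solution and no results are output."""

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class CompartmentInfeasibleError(VvecmoError):
    """No non-negative-tension equilibrium exists for an ideal
    gas-exchange compartment with the given inflows."""


class ConvergenceError(VvecmoError):
    """An iterative solve failed to reach its tolerance."""


class CalibrationError(VvecmoError):
    """A 1-D calibration target could not be bracketed or reached."""


class ConfigError(VvecmoError, ValueError):
    """A scenario configuration is malformed or fails validation."""
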