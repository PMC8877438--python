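"""Exception taxonomy for foulsim."""


class FoulsimError(Exception):
    """Base class for all foulsim errors."""


class ConfigurationError(FoulsimError, ValueError):
    """Invalid user-supplied configuration (unknown species, bad mode name, ...)."""


class InfeasibleCompositionError(ConfigurationError):
    """Requested bulk conductivity below the conductivity of the mandatory background."""


class DomainError(FoulsimError, ValueError):
    """Argument outside the physical domain of a formula (e.g. non-positive radius)."""


class StateError(FoulsimError):
    """A solution state violates its invariants (negative concentrations, charge drift)."""


class SingularFieldError(FoulsimError):
    """Vanishing ionic strength makes the electroneutral electric field undefined."""


class IntegrationError(FoulsimError):
    """The stiff integrator failed to advance the solution."""
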