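"""Exception hierarchy."""


class CisapopError(Exception):
    """Base class for all package errors."""


class NetworkError(CisapopError):
    """Structural problem in a reaction network (unresolved reference etc.)."""


class ConfigurationError(CisapopError):
    """Invalid scenario or scaling configuration."""


class SimulationError(CisapopError):
    """Numerical integration failed.

    Carries the time and state at which the integrator gave up, when known.
    """

    def __init__(self, message, time=None, state=None):
        super().__init__(message)
        self.time = time
        self.state = state
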