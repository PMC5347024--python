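"""Exception hierarchy shared across the package."""


class TumorschedError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(TumorschedError):
    """A scenario, panel or pharmacodynamics table is incomplete or inconsistent."""


class InsufficientDataError(TumorschedError, ValueError):
    """Too few observations for the requested estimate."""


class SimulationOverflowError(TumorschedError, OverflowError):
    """Population counts became non-finite during integration."""

    def __init__(self, time_days: float):
        self.time_days = time_days
        super().__init__(
            f"non-finite cell counts at t = {time_days:g} days; "
            "population overflowed the floating-point range"
        )


class FitConvergenceError(TumorschedError, RuntimeError):
    """Nonlinear dose-response fit failed to converge."""
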