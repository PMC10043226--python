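"""Exception hierarchy shared across the package."""


class EpileptorNetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EpileptorNetError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(EpileptorNetError, ValueError):
    """A numeric input is outside the admissible domain (non-finite, etc.)."""


class IntegrationBlowupError(EpileptorNetError, RuntimeError):
    """A state component exceeded the overflow guard during integration."""

    def __init__(self, step: int, time: float, guard: float):
        self.step = step
        self.time = time
        self.guard = guard
        super().__init__(
            f"integration diverged at step {step} (t = {time:g}): "
            f"a state component left [-{guard:g}, {guard:g}] or became non-finite"
        )


class InsufficientDataError(EpileptorNetError, ValueError):
    """A trajectory or series is too short for the requested analysis."""


class InsufficientEventsError(EpileptorNetError, ValueError):
    """Too few detected seizure events to compute the requested statistic."""


class BracketError(EpileptorNetError, ValueError):
    """A bisection bracket does not straddle the quiescent/oscillatory transition."""


class GenerationError(EpileptorNetError, RuntimeError):
    """A random-graph generator failed to produce an admissible graph."""


class SamplingError(EpileptorNetError, RuntimeError):
    """Rejection sampling exceeded its retry budget."""
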