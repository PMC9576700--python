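"""Exception hierarchy shared across the package."""


class MeaburstError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MeaburstError, ValueError):
    """A configuration or parameter value violates its invariants."""


class InvalidInputError(MeaburstError, ValueError):
    """An input object does not satisfy the preconditions of an operation."""


class DegenerateInputError(MeaburstError, ValueError):
    """Input is structurally valid but carries no usable signal."""


class NumericFailureError(MeaburstError, ArithmeticError):
    """The integrator produced a non-finite state value."""

    def __init__(self, neuron_index: int, t_ms: float):
        self.neuron_index = int(neuron_index)
        self.t_ms = float(t_ms)
        super().__init__(
            f"non-finite state for neuron {neuron_index} at t={t_ms:.3f} ms"
        )


class SimulationRunawayError(MeaburstError, RuntimeError):
    """The network entered a saturated firing regime exceeding the spike
    budget; the run was aborted to bound time and memory."""

    def __init__(self, n_spikes: int, t_ms: float):
        self.n_spikes = int(n_spikes)
        self.t_ms = float(t_ms)
        super().__init__(
            f"spike budget exceeded ({n_spikes} spikes by t={t_ms:.0f} ms); "
            "network is in a runaway regime"
        )


class NoFitError(MeaburstError, RuntimeError):
    """A scan contains no included rows to select a best fit from."""
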