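"""Exception hierarchy for the leechheart package.

Every error raised by the package derives from :class:`LeechHeartError` so
callers can catch package failures with a single except clause.  The
evolutionary search additionally converts simulation/metric failures into
worst-case objective vectors instead of propagating them.
"""


class LeechHeartError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LeechHeartError):
    """A circuit/kinetics configuration is malformed (missing compartment,
    unknown channel label, bad schema)."""


class ValidationError(LeechHeartError):
    """A parameter value violates its contract (off-grid percentage, >100%)."""


class InputError(LeechHeartError):
    """Malformed input data (non-increasing spike times, non-uniform grid)."""


class ParameterError(LeechHeartError):
    """An analysis parameter is out of range (e.g. filter edge >= Nyquist)."""


class SpecificationError(LeechHeartError):
    """A search or generator specification is unsatisfiable."""


class SimulationInstabilityError(LeechHeartError):
    """Numerical divergence (|V| > bound) during integration."""

    def __init__(self, time_s: float, neuron: str, compartment: str):
        self.time_s = time_s
        self.neuron = neuron
        self.compartment = compartment
        super().__init__(
            f"simulation diverged at t={time_s:.4f}s in neuron {neuron}, "
            f"compartment {compartment}"
        )


class InsufficientActivityError(LeechHeartError):
    """Too few bursts to compute metrics (treated as worst case by searches)."""


class InsufficientDataError(LeechHeartError):
    """Too few sweeps for spike-triggered averaging."""


class DegenerateProfileError(LeechHeartError):
    """All-zero synaptic amplitudes for a motor neuron."""


class UndefinedSSIError(LeechHeartError):
    """SSI requested with a zero denominator weight."""


class DegenerateRegressionError(LeechHeartError):
    """Regression requested on a zero-variance predictor."""


class StatisticsError(LeechHeartError):
    """Degenerate input to a statistical test."""


class GenerationError(LeechHeartError):
    """Synthetic-data generation produced degenerate activity."""
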