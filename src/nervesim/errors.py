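"""Exception hierarchy for nervesim."""


class NerveSimError(Exception):
    """Base class for all nervesim errors."""


class InvalidParameterError(NerveSimError, ValueError):
    """A function argument is outside its physical or numerical domain."""


class SingularityError(NerveSimError, ZeroDivisionError):
    """A field or footprint was requested at a source singularity."""


class DomainError(NerveSimError, ValueError):
    """A model was evaluated outside its calibrated domain."""


class SolverFailureError(NerveSimError, RuntimeError):
    """The cable solver produced a non-finite state.

    Carries the compartment index and simulation time at which the
    divergence was first detected.
    """

    def __init__(self, message, compartment=None, time=None):
        super().__init__(message)
        self.compartment = compartment
        self.time = time


class NoPropagationError(NerveSimError, RuntimeError):
    """No action potential was detected where one was required."""


class SearchFailureError(NerveSimError, RuntimeError):
    """A threshold search could not bracket or converge."""


class PackingFailureError(NerveSimError, RuntimeError):
    """The axon-packing iteration terminated with residual overlaps."""

    def __init__(self, message, n_overlaps=None, iterations=None):
        super().__init__(message)
        self.n_overlaps = n_overlaps
        self.iterations = iterations


class ConfigError(NerveSimError, ValueError):
    """A configuration document failed validation."""

    def __init__(self, message, keys=()):
        super().__init__(message)
        self.keys = tuple(keys)


class AlignmentError(NerveSimError, ValueError):
    """Simulation results do not share a common time grid."""


class OptimizerError(NerveSimError, RuntimeError):
    """All candidate evaluations of an optimization run failed."""
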