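"""Exception hierarchy for cardiolab."""


class CardiolabError(Exception):
    """Base class for all cardiolab errors."""


class ConfigurationError(CardiolabError):
    """Invalid configuration: unknown cell type, condition label, scenario, or
    a protocol/grid setting that violates a precondition (e.g. diffusion
    stability bound)."""


class NumericalStateError(CardiolabError):
    """A model state contains non-finite or out-of-range entries."""


class DivergenceError(CardiolabError):
    """The integrator diverged (NaN or membrane potential out of range).

    Carries the name of the offending variable when known.
    """

    def __init__(self, message: str, variable: str | None = None):
        super().__init__(message)
        self.variable = variable


class CaptureError(CardiolabError):
    """Loss of 1:1 capture during pacing; carries the failing beat index."""

    def __init__(self, message: str, beat_index: int | None = None):
        super().__init__(message)
        self.beat_index = beat_index


class UnrepolarizedBeatError(CardiolabError):
    """A beat did not repolarize to the requested fraction before the next
    stimulus (or the end of the trace)."""


class InsufficientDataError(CardiolabError):
    """A measurement was requested on a trace too short to support it."""


class PropagationFailure(CardiolabError):
    """A planar wave failed to traverse a measurement probe.

    This is a meaningful physiological outcome (conduction block), raised as
    an exception so callers must handle it explicitly.
    """


class InsufficientReentryError(CardiolabError):
    """Reentry was not sustained long enough for the requested measurement."""


class ModelFailureError(CardiolabError):
    """Lumped circulation entered an unphysical state (e.g. negative volume)."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


class NotConvergedError(CardiolabError):
    """A run that must reach a periodic steady state did not settle."""


class ProtocolError(CardiolabError):
    """A protocol-level contract violation (e.g. non-periodic drive)."""
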