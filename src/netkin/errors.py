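"""Exception hierarchy shared by all netkin modules."""


class NetkinError(Exception):
    """Base class for all package errors."""


class ParameterError(NetkinError, ValueError):
    """Invalid model or kernel parameter (negative rate, bad exponent, ...)."""


class DomainError(NetkinError, ValueError):
    """A state or field violates its domain constraint (simplex, positivity)."""


class ConfigError(NetkinError, ValueError):
    """Invalid run configuration; the message lists every offending key."""


class SimulationError(NetkinError, RuntimeError):
    """Stochastic simulation failed (non-finite rates, overflow)."""


class StabilityError(NetkinError, RuntimeError):
    """A deterministic solver detected instability (negativity, blow-up).

    Usually resolved by a smaller time step.
    """


class UnsupportedError(NetkinError, NotImplementedError):
    """Requested operation is undefined for the given object (e.g. a local
    limit of a kernel that is not a scaled local kernel)."""
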