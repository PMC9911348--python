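"""Exception hierarchy shared across nsfkit modules."""


class NsfkitError(Exception):
    """Base class for all nsfkit errors."""


class InvalidArgumentError(NsfkitError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class InvalidStateError(NsfkitError, RuntimeError):
    """An internal object is in a state that violates its invariants."""


class NumericalError(NsfkitError, ArithmeticError):
    """A numerical routine failed after all stabilization attempts."""
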