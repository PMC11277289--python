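"""Package-wide error types.

All validation problems raise :class:`ValidationError`; analyses that are
mathematically undefined for the given input (all-zero matrix, zero baseline
power, constant regressors, ...) raise :class:`DegenerateInputError` so callers
can distinguish "bad arguments" from "data that carries no signal".
"""


class GammapatchError(Exception):
    """Base class for all errors raised by gammapatch."""


class ValidationError(GammapatchError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(GammapatchError, ValueError):
    """Input is structurally valid but the requested quantity is undefined."""
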