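"""Exception hierarchy shared across the package."""


class FuncstateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FuncstateError, ValueError):
    """An object or argument violates a structural contract."""


class ParseError(FuncstateError, ValueError):
    """A network file could not be parsed; the message names the offending line."""


class GenerationError(FuncstateError, RuntimeError):
    """A synthetic-network draw could not satisfy its constraints (e.g. connectivity)."""


class DisconnectedError(FuncstateError, ValueError):
    """An operation that needs a connected network received a disconnected one."""
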