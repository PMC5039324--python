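"""Exception hierarchy shared across the package."""


class TransplantxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TransplantxError, ValueError):
    """An argument or simulation parameter violates its contract."""


class DesignError(TransplantxError, ValueError):
    """The sample design is missing treatments or otherwise malformed."""


class FormatError(TransplantxError, ValueError):
    """A file does not conform to its expected on-disk format.

    Always carries enough context (file, line, rule) to locate the problem.
    """

    def __init__(self, message: str, path=None, line=None):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        prefix = f"[{': '.join(ctx)}] " if ctx else ""
        super().__init__(prefix + message)
        self.path = path
        self.line = line


class CrossReferenceError(TransplantxError, KeyError):
    """An identifier in one table is absent from the table it must match."""


class EstimationError(TransplantxError, ValueError):
    """A statistical quantity cannot be estimated from the given data."""


class InsufficientReplicationError(TransplantxError, ValueError):
    """Too few data points for the requested model fit."""
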