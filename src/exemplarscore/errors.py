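"""Exception hierarchy shared across the pipeline stages."""


class ExemplarError(Exception):
    """Base class for all package errors."""


class SchemaError(ExemplarError):
    """Input structure does not match the declared schema (unknown column, bad header)."""


class ValidationError(ExemplarError):
    """A value violates its declared domain or an operation precondition."""


class ConvergenceError(ExemplarError):
    """An iterative fit failed to converge within its iteration budget."""
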