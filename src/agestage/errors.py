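"""Exception hierarchy shared across the package."""


class AgestageError(Exception):
    """Base class for all package errors."""


class SchemaError(AgestageError):
    """Malformed input data: missing columns, bad types, invariant violations."""


class DataError(AgestageError):
    """Structurally valid input that is internally inconsistent."""


class NumericError(AgestageError):
    """A numerical procedure could not produce a result (e.g. no root)."""
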