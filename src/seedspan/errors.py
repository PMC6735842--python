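"""Exception hierarchy shared across modules."""


class SeedspanError(Exception):
    """Base class for all package errors."""


class SchemaError(SeedspanError):
    """Tabular input violates the expected schema (missing column, bad enum...)."""


class InvalidInputError(SeedspanError, ValueError):
    """A scalar argument is outside its domain (e.g. log of a non-positive value)."""


class DegenerateFitError(SeedspanError):
    """A curve fit carries no usable information (no decline, constant data...)."""


class PhylogenyError(SeedspanError):
    """Tree construction, dating or covariance extraction failed."""


class StageError(SeedspanError):
    """A pipeline stage failed; the message names the stage."""
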