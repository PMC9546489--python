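"""Exception types shared across the package."""


class TurbineError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TurbineError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(TurbineError, ValueError):
    """Input data is degenerate (all-zero, constant, ...) for the requested estimate."""


class SchemaError(TurbineError, ValueError):
    """A raw-data file does not conform to the HDF5 schema."""
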