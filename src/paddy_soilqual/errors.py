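"""Exception hierarchy shared across the pipeline."""


class PaddySoilError(Exception):
    """Base class for all package errors."""


class SchemaError(PaddySoilError):
    """A table does not match its declared schema (missing/renamed column)."""


class ParseError(PaddySoilError):
    """A cell could not be parsed as the declared type."""


class ValidationError(PaddySoilError):
    """A row violates a domain invariant (negative mass, pH out of range...)."""


class ConfigError(PaddySoilError):
    """An invalid generator or pipeline configuration."""


class DegenerateSampleError(PaddySoilError):
    """A sample carries no information (zero total mass, all-zero counts)."""


class DegenerateMatrixError(PaddySoilError):
    """A matrix column carries no information (constant, zero denominator)."""
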