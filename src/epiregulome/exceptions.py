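"""Exception types shared across the pipeline."""


class EpiregulomeError(Exception):
    """Base class for all package errors."""


class ConfigError(EpiregulomeError, ValueError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(EpiregulomeError, ValueError):
    """An on-disk table violates its schema; message carries the location."""


class DegenerateDataError(EpiregulomeError, ValueError):
    """Input data is degenerate for the requested operation (constant gene,
    empty cohort, all-junk clustering, ...)."""


class CohortSizeError(EpiregulomeError, ValueError):
    """Cohort too small for module discovery (gate: > 20 samples)."""
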