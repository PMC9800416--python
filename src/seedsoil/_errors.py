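"""Exception hierarchy shared across the package."""


class SeedSoilError(Exception):
    """Base class for all package errors."""


class DataValidationError(SeedSoilError):
    """Malformed or inconsistent input data (bad matrix, labels, file)."""


class AnalysisError(SeedSoilError):
    """A computation cannot proceed (degenerate input, missing class, ...)."""
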