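"""Exception hierarchy shared across the package.

Two broad families matter downstream: configuration/validation problems
(bad inputs, missing coefficient sets — CLI exit code 2) and data-quality
problems (plates whose controls make normalization impossible — exit
code 3).
"""


class PcbToxError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PcbToxError, ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(PcbToxError):
    """A required configuration entry (e.g. a PP-LFER coefficient set) is missing or malformed."""


class DataQualityError(PcbToxError):
    """Plate data is structurally present but unusable (e.g. non-positive control mean)."""


class NormalizationError(DataQualityError):
    """Control wells required for normalization are absent."""


class InsufficientDataError(DataQualityError):
    """Too few distinct concentrations (or replicates) for the requested analysis."""
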