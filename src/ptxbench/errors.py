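"""Package-wide exception types."""


class PtxBenchError(Exception):
    """Base class for all ptxbench errors."""


class ConfigurationError(PtxBenchError, ValueError):
    """Invalid phantom / array / scenario configuration."""


class FieldModelError(PtxBenchError, ValueError):
    """Invalid geometry or inputs for the surrogate field model."""


class FieldFormatError(PtxBenchError, ValueError):
    """Malformed field container on disk."""


class SarUnavailableError(PtxBenchError, RuntimeError):
    """SAR was requested but no E-field data is available."""


class OptimizationError(PtxBenchError, RuntimeError):
    """An optimizer failed to produce a usable result."""
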