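"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2,
DataValidationError (incl. SizingError) -> 3, anything else -> 4.
"""


class PipelineError(Exception):
    """Base class for all phagecarbon errors."""


class ConfigError(PipelineError):
    """Invalid or missing configuration."""


class DataValidationError(PipelineError):
    """Input data violates a documented contract."""


class SizingError(DataValidationError):
    """A contig is too short to host a requested planted feature."""
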