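"""Exception hierarchy shared across the package."""


class StressclustError(Exception):
    """Base class for all package errors."""


class ConfigError(StressclustError):
    """Invalid configuration value; message names the offending field."""


class ParseError(StressclustError):
    """Malformed input file; message carries row/column or line coordinates."""


class PipelineError(StressclustError):
    """A pipeline stage failed; message names the stage."""
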