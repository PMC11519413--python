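"""Exception hierarchy shared across the pipeline stages."""


class NephrometryError(Exception):
    """Base class for all package errors."""


class ConfigError(NephrometryError):
    """Invalid configuration; the message names the offending field."""


class DataError(NephrometryError):
    """Input data violates an invariant; the message names the row/column."""


class PipelineError(NephrometryError):
    """A pipeline stage failed or its output is missing."""
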