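"""Package exceptions."""


class TpopvError(Exception):
    """Base class for package errors."""


class ConfigurationError(TpopvError):
    """Invalid configuration (non-normalizable weights, bad role set, ...)."""


class FormatError(TpopvError):
    """A raw table file does not conform to the expected dialect."""


class PipelineError(TpopvError):
    """A pipeline stage failed; message carries the stage name and context."""
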