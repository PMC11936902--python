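"""Exception hierarchy shared across the package."""


class LungregError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LungregError, ValueError):
    """Invalid configuration object or parameter range."""


class FormatError(LungregError, ValueError):
    """Unreadable or malformed file; message carries the path."""


class ContractError(LungregError, ValueError):
    """An operation was called in a way its contract forbids."""


class PipelineError(LungregError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
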