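"""Exception hierarchy shared across the package."""


class FlexitrimError(Exception):
    """Base class for all package errors."""


class ParseError(FlexitrimError):
    """A sequence file could not be parsed in the declared format."""


class ConfigError(FlexitrimError):
    """Inconsistent or unsupported configuration."""


class PairingError(FlexitrimError):
    """Paired input files disagree on record count."""


class EncodingError(FlexitrimError):
    """A sequence cannot be converted between letter and color space."""


class EvaluationError(FlexitrimError):
    """Truth table and demultiplexing output cannot be matched up."""
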