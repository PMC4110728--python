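"""Exception hierarchy shared across the toolkit."""


class MateSVError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MateSVError):
    """Malformed input file (SAM/BEDPE/BED/...)."""


class ModelError(MateSVError):
    """Insert-size model cannot be built from the given pairs."""


class ParameterError(MateSVError):
    """Invalid user-supplied parameter combination."""


class ConfigError(MateSVError):
    """Invalid simulation or caller configuration."""
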