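"""Exception hierarchy shared across the pipeline stages."""


class FeatfuseError(Exception):
    """Base class for all featfuse errors."""


class InvalidInputError(FeatfuseError, ValueError):
    """An operation received data violating its preconditions."""


class NoForegroundError(InvalidInputError):
    """A mask contains no foreground pixels."""


class SelectionInfeasibleError(FeatfuseError):
    """Fewer distinct extractor families than requested selections."""


class ConfigError(FeatfuseError):
    """A run configuration is malformed (unknown key or invalid value)."""


class DataError(FeatfuseError):
    """An input file is missing, malformed, or misaligned."""
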