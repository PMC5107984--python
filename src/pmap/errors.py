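"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
StageError -> 4.
"""


class PmapError(Exception):
    """Base class for all pmap errors."""


class ConfigError(PmapError):
    """Invalid configuration or parameters."""


class DataError(PmapError):
    """Malformed or inconsistent input data."""


class StageError(PmapError):
    """A pipeline stage failed."""
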