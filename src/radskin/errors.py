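"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class RadskinError(Exception):
    """Base class for all package errors."""


class ConfigError(RadskinError):
    """Invalid configuration (bad thresholds, inconsistent simulation setup...)."""


class DataError(RadskinError):
    """Malformed or inconsistent input data (ragged TSV, duplicate probes...)."""


class GroupAbsentError(DataError):
    """A requested (dose, timepoint) group has no samples in the matrix."""
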