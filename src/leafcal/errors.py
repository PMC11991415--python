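"""Exception hierarchy for the leafcal pipeline.

Schema problems (bad CSV files, wrong channel counts) and computation
problems (degenerate references, too few replicates) raise distinct,
named exceptions so callers and the CLI can map them to exit codes.
"""


class LeafcalError(Exception):
    """Base class for all leafcal errors."""


class ConfigError(LeafcalError, ValueError):
    """Invalid run configuration (bad sizes, unknown mode, ...)."""


class SchemaError(LeafcalError, ValueError):
    """A table does not match its declared schema."""


class MissingColumnError(SchemaError):
    """A required column is absent from an input table."""


class ChannelCountError(SchemaError):
    """The channel columns of a table do not match the sensor layout."""


class NegativeCountError(SchemaError):
    """Raw sensor counts are negative."""


class UnknownSensorError(SchemaError):
    """A sensor/layout name is not one of the known layouts."""


class DegenerateReferenceError(LeafcalError, ValueError):
    """A white-reference channel is zero or negative, so reflectance is undefined."""


class InsufficientDataError(LeafcalError, ValueError):
    """Too few rows/replicates/disks for the requested computation."""


class ReplicateCountError(LeafcalError, ValueError):
    """A leaf does not have exactly the expected number of replicates."""


class StratificationError(LeafcalError, ValueError):
    """A quantile bin has too few leaves to satisfy the requested split."""


class PerfectFitError(LeafcalError, ValueError):
    """RSS of zero: AIC is minus infinity and undefined."""
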