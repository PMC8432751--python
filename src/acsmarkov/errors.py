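"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or run configuration parameter is invalid."""


class SchemaError(ValueError):
    """An input table is missing a required column or has the wrong shape."""


class DataError(ValueError):
    """A row-level value violates its domain (e.g. negative days supply)."""


class ClassificationError(ValueError):
    """A death record cannot be assigned a cause category."""


class MatchingError(ValueError):
    """Matched-control construction cannot proceed (e.g. empty pool)."""


class ElicitationError(ValueError):
    """An expert summary cannot support the requested prior fit."""
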