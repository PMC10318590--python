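"""Exception types shared across the package."""


class RowsegError(Exception):
    """Base class for all package errors."""


class ConfigError(RowsegError):
    """A configuration value is invalid; the message names the offending field."""


class GeometryError(RowsegError):
    """A box or grid operation cannot be completed (e.g. over-trimming)."""


class DataError(RowsegError):
    """Input data violate a precondition (missing dates, bands, cells...)."""
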