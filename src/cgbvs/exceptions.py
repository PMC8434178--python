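"""Exception hierarchy shared across the package."""


class CGBVSError(Exception):
    """Base class for all package errors."""


class DataError(CGBVSError):
    """Invalid or inconsistent input data (files, tables, matrices)."""


class ConfigError(CGBVSError):
    """Invalid run configuration."""
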