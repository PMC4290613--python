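"""Exception hierarchy shared across the package."""


class GQSARError(Exception):
    """Base class for all package errors."""


class SubstituentError(GQSARError):
    """A fragment violates the substituent conventions (dummy count, parse failure)."""


class AssemblyError(GQSARError):
    """Scaffold + substituent assembly produced an invalid molecule."""


class DataError(GQSARError):
    """Malformed or inconsistent input data (series tables, pools, descriptor matrices)."""


class ConfigError(GQSARError):
    """Invalid run configuration or model settings."""
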