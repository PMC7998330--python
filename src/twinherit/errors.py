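"""Exception hierarchy shared across the package."""


class TwinheritError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TwinheritError):
    """Invalid configuration (schema map, simulation settings, CLI options)."""


class DataError(TwinheritError):
    """Invalid or inconsistent cohort data (missing columns, bad pairs, parse failures)."""


class FitError(TwinheritError):
    """Model fitting failed in a way that cannot be expressed as a non-converged fit."""
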