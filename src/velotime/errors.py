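"""Exception types shared across the package.

Error messages start with a stable, machine-readable token (e.g.
``layer-missing: unspliced``) so callers and the CLI can match on them.
"""


class VelotimeError(ValueError):
    """Base class for all package-specific errors."""


class DataError(VelotimeError):
    """Malformed or inconsistent input data."""


class ConfigError(VelotimeError):
    """Invalid configuration value."""


class TrainingError(VelotimeError):
    """Optimization failure (e.g. divergence)."""
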