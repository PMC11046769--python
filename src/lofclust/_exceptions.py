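"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigurationError -> 2,
ValidationError -> 3, NumericalError -> 4.
"""


class LofclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LofclustError):
    """A run configuration or model hyper-parameter is unusable."""


class ValidationError(LofclustError):
    """Input data violates a documented contract."""


class NumericalError(LofclustError):
    """A numerical routine failed to produce a usable result."""
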