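"""Exception hierarchy shared by all modules."""


class SpikeSortError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SpikeSortError, ValueError):
    """Raised when data passed to an operation violates its preconditions."""


class ConfigurationError(SpikeSortError, ValueError):
    """Raised when a configuration value violates a type invariant."""
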