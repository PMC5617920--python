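"""Exception hierarchy shared by all hoxspring modules."""


class HoxspringError(Exception):
    """Base class for all package errors."""


class ParameterError(HoxspringError, ValueError):
    """A physical or model parameter violates its invariant."""


class ConfigurationError(HoxspringError, ValueError):
    """A run configuration (grid, timestep, config file) is invalid."""


class InputError(HoxspringError, ValueError):
    """Malformed runtime input (empty grids, unknown gene names, ...)."""
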