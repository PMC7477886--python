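"""Exception types shared across the package."""


class MccspError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(MccspError, ValueError):
    """An estimator received input it cannot work with (e.g. a constant vector)."""


class NetworkStructureError(MccspError, ValueError):
    """The supplied network violates a structural requirement (cycle, missing edge, ...)."""


class ConfigurationError(MccspError, ValueError):
    """A run configuration is inconsistent or incomplete."""
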