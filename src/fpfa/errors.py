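"""Exception hierarchy shared across the package."""


class FpfaError(Exception):
    """Base class for all fpfa errors."""


class FormatError(FpfaError):
    """Unknown or malformed on-disk photon format."""


class SchemaError(FpfaError):
    """A required metadata key or column is missing."""


class ValidationError(FpfaError):
    """A photon record or parameter violates an invariant."""


class SimulationSizeError(FpfaError):
    """A simulation request implies an unreasonable number of photons."""


class FitError(FpfaError):
    """A fit could not be set up (bad window, empty data, ...)."""
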