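"""Exception and warning types used across the package."""


class KMReconError(Exception):
    """Base class for all kmrecon errors."""


class InputFormatError(KMReconError, ValueError):
    """An input file or table violates the expected layout or conventions."""


class ConsistencyError(KMReconError, ValueError):
    """Inputs are individually well formed but mutually inconsistent."""


class ConfigurationError(KMReconError, ValueError):
    """The requested information level does not match the supplied inputs."""


class ReconstructionWarning(UserWarning):
    """Non-fatal condition met while reconstructing (clamping, non-convergence)."""


class RepairWarning(UserWarning):
    """A digitized curve anomaly was repaired automatically."""
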