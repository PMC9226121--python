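"""Exception hierarchy for wavenav.

All package errors derive from :class:`WavenavError` so callers can catch
everything with one except clause; the CLI maps subclasses to exit codes.
"""


class WavenavError(Exception):
    """Base class for all wavenav errors."""


class ConfigurationError(WavenavError):
    """Invalid configuration value, file, or dimension mismatch."""


class DegenerateManifoldError(ConfigurationError):
    """Grid has too few free nodes to define a planning problem."""


class DegenerateMazeError(ConfigurationError):
    """Start and target are not mutually reachable on the masked grid."""


class InvalidNodeError(WavenavError):
    """A node id/coordinate is blocked or outside the grid."""


class CollapsedBumpError(WavenavError):
    """Total activation of the attractor sheet reached zero: the bump is lost."""


class NumericalDivergenceError(WavenavError):
    """A state variable became non-finite during integration."""


class InitializationError(WavenavError):
    """Bump relaxation failed to converge within its step budget."""
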