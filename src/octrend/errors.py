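"""Exception hierarchy.

All pipeline stages raise subclasses of :class:`OctrendError`, so callers can
distinguish configuration mistakes from data problems and numerical failures
(the CLI maps these onto distinct exit codes).
"""


class OctrendError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OctrendError):
    """Invalid user-supplied configuration (bad covariance, |rho| >= 1, ...)."""


class InsufficientDataError(OctrendError):
    """Too few unmasked time steps for the requested estimate."""


class GeometryError(OctrendError):
    """Grids that do not nest or coordinates that do not align."""


class FormatError(OctrendError):
    """A file that lacks the coordinates/variables a cube requires."""


class ExtrapolationError(OctrendError):
    """A requested band centre lies outside the model wavelength grid."""
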