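"""Exception hierarchy shared across the package."""


class IgmHingeError(Exception):
    """Base class for all package-specific errors."""


class ModelParseError(IgmHingeError):
    """A structure file could not be parsed."""


class EmptyModelError(IgmHingeError):
    """A structure file contained no atoms."""


class SelectionError(IgmHingeError):
    """A domain selection matched no atoms or is malformed."""


class AtomAddressError(IgmHingeError):
    """A (chain, residue, atom-name) address does not exist in the model."""


class PairingError(IgmHingeError):
    """Atom pairing for superposition failed (mismatched or too few pairs)."""


class SymmetryError(IgmHingeError):
    """A selection expected to be a two-fold dimer is not."""


class DegenerateGeometryError(IgmHingeError):
    """A direction or frame is degenerate (zero length, undefined angle)."""


class GridBoundsError(IgmHingeError):
    """Atoms fall outside the density grid (with the required margin)."""


class GridMismatchError(IgmHingeError):
    """Two density maps do not share the same grid geometry."""


class GeometryError(IgmHingeError):
    """A plane or ring does not intersect the available data."""


class DegenerateFitError(IgmHingeError):
    """Circle fit input is collinear or otherwise degenerate."""


class SamplingError(IgmHingeError):
    """Too few pixels/frames to compute a statistic."""


class DegenerateBackgroundError(IgmHingeError):
    """Background standard deviation is zero; SNR ratio undefined."""


class NoSignalError(IgmHingeError):
    """Profile never exceeds the detection threshold."""


class WindowTooSmallError(IgmHingeError):
    """Profile never falls below the threshold inside the scanned window."""

    def __init__(self, message, edge_angle=None):
        super().__init__(message)
        self.edge_angle = edge_angle


class NoRecoveryError(IgmHingeError):
    """Donor intensity did not recover after acceptor photobleaching."""


class BuriedSiteError(IgmHingeError):
    """Accessible-volume calculation found no sterically allowed positions."""


class FitError(IgmHingeError):
    """A statistical fit failed to converge."""


class ConfigError(IgmHingeError):
    """A run configuration is invalid."""
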