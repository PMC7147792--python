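"""Exception hierarchy for sashamap."""


class SashaMapError(Exception):
    """Base class for all sashamap errors."""


class PlacementError(SashaMapError):
    """Phantom regions cannot be placed without overlap or out of bounds."""


class GeometryError(SashaMapError):
    """Requested geometry does not fit the voxel grid or is degenerate."""


class ScheduleError(SashaMapError):
    """Invalid saturation-time schedule."""


class DataError(SashaMapError):
    """Input data violates a contract (shape, sign, finiteness, emptiness)."""


class SolverError(SashaMapError):
    """Iterative solver failed (non-finite energy, persistent divergence)."""


class FormatError(SashaMapError):
    """On-disk representation inconsistent with its sidecar metadata."""
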