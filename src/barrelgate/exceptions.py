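"""Exception hierarchy for barrelgate."""


class BarrelgateError(Exception):
    """Base class for all barrelgate errors."""


class PDBParseError(BarrelgateError):
    """A PDB record could not be parsed."""


class TrajectoryConsistencyError(BarrelgateError):
    """Frames of a trajectory do not share a common atom set."""


class SelectionError(BarrelgateError):
    """An atom/residue selection is malformed or cannot be resolved."""


class DegenerateGeometryError(BarrelgateError):
    """A geometric operation received degenerate input (collinear, too few points)."""


class ScoreRangeError(BarrelgateError):
    """A per-atom score does not fit the B-factor column."""


class MappingError(BarrelgateError):
    """A residue-keyed annotation refers to a residue absent from the structure."""


class ConfigError(BarrelgateError):
    """A run configuration is invalid or incomplete."""
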