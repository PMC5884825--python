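"""Exception hierarchy shared across the package."""


class TrajnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TrajnetError):
    """A synthetic-data specification cannot be realised (e.g. unrepairable
    correlation matrix, too few frames)."""


class StructureFormatError(TrajnetError):
    """A structure file could not be parsed into Cα records."""


class TrajectoryFormatError(TrajnetError):
    """A trajectory file is malformed (frame/atom-count mismatch, truncation)."""


class DegenerateSelectionError(TrajnetError):
    """A superposition selection is too degenerate to define a fit."""


class DomainResolutionError(TrajnetError):
    """A named residue range resolves to no residues in the structure."""


class FitError(TrajnetError):
    """A power-law fit is infeasible on the supplied data."""


class StageError(TrajnetError):
    """A pipeline stage failed; carries the stage name for provenance."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
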