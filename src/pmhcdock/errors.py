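"""Exception hierarchy for the pMHC-I modelling toolkit."""


class PmhcdockError(Exception):
    """Base class for all package errors."""


class PdbFormatError(PmhcdockError):
    """A coordinate file could not be interpreted as PDB."""


class StructureError(PmhcdockError):
    """Invalid or degenerate structure content."""


class RoleAssignmentError(StructureError):
    """Chain roles (peptide / heavy chain / beta-2-microglobulin) not assignable."""


class AmbiguousPeptideError(RoleAssignmentError):
    """Two or more equally short peptide-length chains."""


class EmptySelectionError(StructureError):
    """An atom selection matched nothing."""


class SequenceError(PmhcdockError):
    """Epitope sequence outside the 20-letter amino-acid alphabet or wrong length."""


class GeometryError(PmhcdockError):
    """Degenerate geometry (too few atoms, collinear sets, length mismatch)."""


class ConsensusError(PmhcdockError):
    """Pose-ensemble consensus cannot be computed (e.g. empty ensemble)."""


class BackendError(PmhcdockError):
    """A docking or energy-minimization backend failed.

    ``stage`` labels the pipeline stage at which the failure occurred.
    """

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class BackendUnavailableError(BackendError):
    """The external engine executable is not installed."""


class PipelineError(PmhcdockError):
    """Unrecoverable pipeline-level failure."""


class FixtureError(PmhcdockError):
    """A synthetic-fixture generator could not satisfy its guarantee."""
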