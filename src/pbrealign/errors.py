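"""Exception hierarchy for pbrealign."""


class PBRealignError(Exception):
    """Base class for all pbrealign errors."""


class ChainNotFoundError(PBRealignError):
    """Requested chain identifier is absent from the structure file."""


class EmptyChainError(PBRealignError):
    """Chain contains no residue with a complete N/CA/C backbone."""


class UndefinedDihedralError(PBRealignError):
    """Dihedral geometry is degenerate (coincident or collinear points)."""


class AlignmentFormatError(PBRealignError):
    """Pairwise alignment input violates the two-record gapped-FASTA contract."""


class SequenceMismatchError(PBRealignError):
    """Ungapped alignment row disagrees with the chain's residue sequence."""


class DegenerateGeometryError(PBRealignError):
    """Too few or collinear points for a rigid-body superposition."""
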