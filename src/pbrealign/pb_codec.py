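"""Backbone dihedrals and Protein Block (PB) encoding.

A Protein Block is one of 16 canonical five-residue backbone conformations,
labelled ``a``..``p``.  Each block is defined by a reference vector of eight
dihedral angles — psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1),
psi(i+1), phi(i+2) — so a protein backbone can be rewritten as a 1D string
over the 16-letter structural alphabet.  Assignment slides a five-residue
window along the chain and picks, at every position where all eight window
dihedrals are defined, the letter whose reference vector minimises the root
mean square of wrapped angular differences (RMSDA).

Positions without a complete window (the two residues at either terminus,
and positions adjacent to chain breaks) carry the unassigned sentinel ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import UndefinedDihedralError
from .structure_io import BackboneChain

PB_ALPHABET = "abcdefghijklmnop"
UNASSIGNED = "Z"

#: CA-CA distance above which two consecutive residues are treated as a
#: chain break; generous bound above trans (3.8 A) and cis (~2.9 A) peptides.
CHAIN_BREAK_CA_DISTANCE = 4.5

_DEFAULT_DEFS = "pb_reference_angles.tsv"


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, in degrees in (-180, 180].

    IUPAC sign convention: 0 for cis, 180 for trans, sign by the right-hand
    rule looking down the p2->p3 bond.

    Raises
    ------
    UndefinedDihedralError
        If consecutive points coincide or p1..p3 / p2..p4 are collinear,
        which leaves the angle undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedDihedralError("degenerate geometry: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2 / b2n), n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass(frozen=True)
class DihedralSeries:
    """Per-residue phi/psi angles; NaN marks an undefined angle."""

    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def compute_dihedrals(chain: BackboneChain) -> DihedralSeries:
    """phi/psi series of a backbone chain.

    phi(i) is C(i-1)-N(i)-CA(i)-C(i); psi(i) is N(i)-CA(i)-C(i)-N(i+1).
    phi is undefined at the first residue and psi at the last.  Consecutive
    residues whose CA atoms are further apart than
    :data:`CHAIN_BREAK_CA_DISTANCE` are treated as a chain break: the
    dihedrals spanning the break (phi of the downstream residue, psi of the
    upstream one) are undefined.
    """
    n = len(chain)
    if n < 2:
        raise ValueError("need at least 2 residues for any dihedral")
    N, CA, C = chain.coords("N"), chain.coords("CA"), chain.coords("C")
    broken_after = (
        np.linalg.norm(CA[1:] - CA[:-1], axis=1) > CHAIN_BREAK_CA_DISTANCE
    )  # break between i and i+1
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0 and not broken_after[i - 1]:
            try:
                phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
            except UndefinedDihedralError:
                pass
        if i < n - 1 and not broken_after[i]:
            try:
                psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
            except UndefinedDihedralError:
                pass
    return DihedralSeries(phi=phi, psi=psi)


def wrap_angle_difference(a, b):
    """Absolute angular difference wrapped into [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def rmsda(window, reference) -> float:
    """Root mean square of wrapped angular differences over 8 dihedrals.

    The PB assignment dissimilarity: sqrt(mean of squared wrapped
    differences), each difference in [0, 180] degrees.

    Raises
    ------
    ValueError
        If either vector contains an undefined (NaN) angle.
    """
    w = np.asarray(window, dtype=float)
    r = np.asarray(reference, dtype=float)
    if w.shape != (8,) or r.shape != (8,):
        raise ValueError("rmsda expects two 8-angle vectors")
    if np.isnan(w).any() or np.isnan(r).any():
        raise ValueError("rmsda requires all 16 angles to be defined")
    d = wrap_angle_difference(w, r)
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class PBDefinitions:
    """The 16 PB reference vectors, rows ordered a..p."""

    letters: str
    vectors: np.ndarray  # (16, 8) degrees

    def __post_init__(self):
        if self.letters != PB_ALPHABET:
            raise ValueError("PB definitions must cover exactly a..p in order")
        if self.vectors.shape != (16, 8):
            raise ValueError("expected a 16x8 angle table")
        if not ((self.vectors > -180.0) & (self.vectors <= 180.0)).all():
            raise ValueError("reference angles must lie in (-180, 180]")

    def vector(self, letter: str) -> np.ndarray:
        return self.vectors[PB_ALPHABET.index(letter)]

    def central_phi_psi(self, letter: str) -> tuple[float, float]:
        """(phi, psi) of the window's central residue — handy for rebuilding
        an idealised backbone from a PB string."""
        v = self.vector(letter)
        return float(v[3]), float(v[4])

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PBDefinitions":
        """Load reference vectors from a TSV (bundled table by default)."""
        if path is None:
            src = resources.files("pbrealign.data") / _DEFAULT_DEFS
            text = src.read_text()
        else:
            text = Path(path).read_text()
        letters = []
        rows = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            letters.append(parts[0])
            rows.append([float(x) for x in parts[1:9]])
        return cls(letters="".join(letters), vectors=np.array(rows))


def _window(series: DihedralSeries, i: int) -> np.ndarray:
    """Eight-angle window centred on residue i (NaN where undefined)."""
    n = len(series)
    if i < 2 or i > n - 3:
        return np.full(8, np.nan)
    phi, psi = series.phi, series.psi
    return np.array(
        [psi[i - 2], phi[i - 1], psi[i - 1], phi[i], psi[i],
         phi[i + 1], psi[i + 1], phi[i + 2]]
    )


def assign_pbs(series: DihedralSeries, defs: PBDefinitions | None = None) -> str:
    """Encode a dihedral series as a PB string.

    Each position with a complete 8-angle window gets the letter minimising
    :func:`rmsda` against the 16 reference vectors; ties break alphabetically.
    Everything else (the two positions at each end, break neighbourhoods) is
    ``Z``.
    """
    if defs is None:
        defs = PBDefinitions.load()
    out = []
    for i in range(len(series)):
        w = _window(series, i)
        if np.isnan(w).any():
            out.append(UNASSIGNED)
            continue
        d = wrap_angle_difference(w[None, :], defs.vectors)
        scores = np.sqrt(np.mean(d * d, axis=1))
        out.append(PB_ALPHABET[int(np.argmin(scores))])
    return "".join(out)


def encode_chain(chain: BackboneChain, defs: PBDefinitions | None = None) -> str:
    """Convenience: chain -> dihedrals -> PB string."""
    return assign_pbs(compute_dihedrals(chain), defs)
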