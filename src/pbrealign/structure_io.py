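"""Reading backbones from PDB/mmCIF files and writing superposed pairs.

Only the N, CA and C atoms are kept — they are all that phi/psi (and hence
PB encoding) need.  Residues missing any of the three are dropped with a
logged warning; HETATM residues are excluded; alternate locations resolve to
the highest-occupancy conformer (ties keep the first in file order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import ChainNotFoundError, EmptyChainError

log = logging.getLogger(__name__)

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C")


def three_to_one(resname: str) -> str:
    """Three-letter residue name to one-letter code ('X' if non-standard)."""
    return _AA3_TO_1.get(resname.upper(), "X")


def one_to_three(code: str) -> str:
    return _AA1_TO_3.get(code.upper(), "UNK")


@dataclass(frozen=True)
class Residue:
    """One residue's backbone: author numbering plus N/CA/C coordinates (A)."""

    residue_number: int
    insertion_code: str
    amino_acid: str
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray

    def atom(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class BackboneChain:
    """An ordered backbone chain; internal indexing is 0-based sequential,
    author numbering is preserved per residue for reporting."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) coordinates of one backbone atom type."""
        if atom not in BACKBONE_ATOMS:
            raise ValueError(f"unknown backbone atom {atom!r}")
        return np.array([r.atom(atom) for r in self.residues], dtype=float)

    def all_coords(self) -> np.ndarray:
        """(3n, 3) N/CA/C coordinates in residue order."""
        return np.array(
            [r.atom(a) for r in self.residues for a in BACKBONE_ATOMS], dtype=float
        )


def _pick_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Highest-occupancy atom of a given name (ties -> first in file)."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_backbone(
    path: str | Path, chain_id: str, model_index: int = 0
) -> BackboneChain:
    """Extract one chain's N/CA/C backbone from a PDB or mmCIF file.

    Parameters
    ----------
    path : structure file (format inferred from contents/extension by gemmi)
    chain_id : author chain identifier
    model_index : 0-based model to use (first model by default)

    Raises
    ------
    FileNotFoundError, ChainNotFoundError, EmptyChainError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if model_index >= len(structure):
        raise ValueError(f"model index {model_index} out of range ({len(structure)} models)")
    model = structure[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        known = ", ".join(c.name for c in model) or "<none>"
        raise ChainNotFoundError(
            f"chain {chain_id!r} not in {path.name} (chains: {known})"
        )
    residues: list[Residue] = []
    seen = 0
    for res in chain:
        if res.het_flag == "H":
            continue
        seen += 1
        atoms = {name: _pick_atom(res, name) for name in BACKBONE_ATOMS}
        missing = [name for name, a in atoms.items() if a is None]
        if missing:
            log.warning(
                "dropping %s %s%s in chain %s: missing backbone atom(s) %s",
                res.name, res.seqid.num, (res.seqid.icode or "").strip(),
                chain_id, ",".join(missing),
            )
            continue
        residues.append(
            Residue(
                residue_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                amino_acid=three_to_one(res.name),
                N=np.array(atoms["N"].pos.tolist()),
                CA=np.array(atoms["CA"].pos.tolist()),
                C=np.array(atoms["C"].pos.tolist()),
            )
        )
    if not residues:
        raise EmptyChainError(
            f"chain {chain_id!r} in {path.name}: no residue with a complete "
            f"N/CA/C backbone among {seen} polymer residues"
        )
    return BackboneChain(chain_id=chain_id, residues=residues)


def _chain_to_gemmi(chain: BackboneChain, chain_name: str) -> gemmi.Chain:
    gchain = gemmi.Chain(chain_name)
    for res in chain.residues:
        gres = gemmi.Residue()
        gres.name = one_to_three(res.amino_acid)
        gres.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
        gres.het_flag = "A"
        for name, element in zip(BACKBONE_ATOMS, ("N", "C", "C")):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.occ = 1.0
            atom.b_iso = 0.0
            xyz = res.atom(name)
            atom.pos = gemmi.Position(*(float(v) for v in xyz))
            gres.add_atom(atom)
        gchain.add_residue(gres)
    return gchain


def write_backbone_pdb(chain: BackboneChain, path: str | Path, chain_name: str | None = None) -> None:
    """Write a single backbone chain as a PDB file (coordinates to 3 dp)."""
    structure = gemmi.Structure()
    model = gemmi.Model(1)
    model.add_chain(_chain_to_gemmi(chain, chain_name or chain.chain_id or "A"))
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def transform_chain(chain: BackboneChain, rotation: np.ndarray, translation: np.ndarray) -> BackboneChain:
    """Return a copy of the chain with x -> R x + t applied to every atom."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    moved = [
        Residue(
            residue_number=r.residue_number,
            insertion_code=r.insertion_code,
            amino_acid=r.amino_acid,
            N=R @ r.N + t,
            CA=R @ r.CA + t,
            C=R @ r.C + t,
        )
        for r in chain.residues
    ]
    return BackboneChain(chain_id=chain.chain_id, residues=moved)


def write_superposed(
    chain_a: BackboneChain,
    chain_b: BackboneChain,
    transform,
    path: str | Path,
) -> None:
    """Write chain A unchanged and chain B with the rigid transform applied,
    as a two-chain PDB file.

    Chain identifiers in the output are "A" and "B" regardless of the input
    identifiers, so the pair is unambiguous in viewers.
    """
    moved_b = transform_chain(chain_b, transform.rotation, transform.translation)
    structure = gemmi.Structure()
    model = gemmi.Model(1)
    model.add_chain(_chain_to_gemmi(chain_a, "A"))
    model.add_chain(_chain_to_gemmi(moved_b, "B"))
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
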