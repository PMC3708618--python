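"""Synthetic backbones and homolog pairs with known ground truth.

Chains are built from a per-residue (phi, psi) script by sequential
internal-coordinate placement (the NeRF construction) with idealised
trans-peptide covalent geometry, so :func:`pbrealign.pb_codec.compute_dihedrals`
recovers the script exactly and every stage of the pipeline can be tested
against a constructed truth.

The homolog-pair generator reproduces the phenomenon the method targets:
``rigid_rotate_loop`` displaces a span by a rigid rotation about the axis
through its two hinge CA atoms — the span's internal conformation (hence
its interior PB letters) is untouched while its global position moves by
several angstroms, i.e. a conformationally similar SVR.  ``change_dihedrals``
rewrites the span's backbone dihedrals and splices the rebuilt fragment onto
the left hinge, producing a genuinely dissimilar SVR.  Insertions and
deletions are supported for gap-bearing alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .alignment_model import PairwiseAlignment
from .pb_codec import PBDefinitions
from .segmentation import Region
from .structure_io import BackboneChain, Residue


@dataclass(frozen=True)
class BackboneGeometry:
    """Idealised covalent geometry for chain building (A / degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    angle_c_n_ca: float = 121.7  # at N
    angle_n_ca_c: float = 111.2  # at CA
    angle_ca_c_n: float = 116.2  # at C
    omega: float = 180.0

    def __post_init__(self):
        for v in (self.n_ca, self.ca_c, self.c_n):
            if not 1.0 < v < 2.0:
                raise ValueError("bond lengths must lie in (1, 2) A")
        for v in (self.angle_c_n_ca, self.angle_n_ca_c, self.angle_ca_c_n):
            if not 90.0 < v < 150.0:
                raise ValueError("bond angles must lie in (90, 150) degrees")


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, the C-D bond length, the B-C-D angle and
    the A-B-C-D torsion (NeRF internal-to-Cartesian step)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    u = c - b
    u /= np.linalg.norm(u)
    n = np.cross(b - a, u)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear support atoms: torsion frame undefined")
    n /= nn
    m = np.cross(n, u)
    # the minus sign on the out-of-plane term matches the IUPAC right-hand
    # sign convention used by pb_codec.dihedral
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), -np.sin(theta) * np.sin(tau)]
    )
    return c + d_local[0] * u + d_local[1] * m + d_local[2] * n


def build_backbone(
    script,
    geometry: BackboneGeometry = BackboneGeometry(),
    sequence: str | None = None,
    chain_id: str = "A",
) -> BackboneChain:
    """Build an N/CA/C backbone from a per-residue (phi, psi) script.

    ``script[0]``'s phi and ``script[-1]``'s psi are not used (those
    dihedrals do not exist).  Residues are poly-alanine unless a sequence
    is given.
    """
    script = [(float(p), float(s)) for p, s in script]
    n = len(script)
    if n < 2:
        raise ValueError("script must cover at least 2 residues")
    if sequence is not None and len(sequence) != n:
        raise ValueError("sequence length must match script length")
    g = geometry
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([g.n_ca, 0.0, 0.0])]
    theta = np.radians(g.angle_n_ca_c)
    C = [CA[0] + g.ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0])]
    for i in range(n - 1):
        psi_i = script[i][1]
        phi_next = script[i + 1][0]
        N.append(place_atom(N[i], CA[i], C[i], g.c_n, g.angle_ca_c_n, psi_i))
        CA.append(place_atom(CA[i], C[i], N[i + 1], g.n_ca, g.angle_c_n_ca, g.omega))
        C.append(place_atom(C[i], N[i + 1], CA[i + 1], g.ca_c, g.angle_n_ca_c, phi_next))
    residues = [
        Residue(
            residue_number=i + 1,
            insertion_code="",
            amino_acid=(sequence[i] if sequence else "A"),
            N=N[i], CA=CA[i], C=C[i],
        )
        for i in range(n)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues)


def script_from_pbs(pb_string: str, defs: PBDefinitions | None = None) -> list:
    """(phi, psi) script using each PB letter's central reference dihedrals."""
    if defs is None:
        defs = PBDefinitions.load()
    return [defs.central_phi_psi(ch) for ch in pb_string]


def fragment_script(letter: str, defs: PBDefinitions | None = None) -> list:
    """The five-residue (phi, psi) script of one PB's full reference vector.

    The vector's eight angles cover residues i-2..i+2 of the window:
    psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i), phi(i+1), psi(i+1),
    phi(i+2).  The two angles the vector does not constrain (phi of the
    first residue, psi of the last) are irrelevant to the window and set to
    the central values.
    """
    if defs is None:
        defs = PBDefinitions.load()
    v = defs.vector(letter)
    return [
        (float(v[3]), float(v[0])),
        (float(v[1]), float(v[2])),
        (float(v[3]), float(v[4])),
        (float(v[5]), float(v[6])),
        (float(v[7]), float(v[4])),
    ]


def reference_chain(
    letter: str, length: int = 12, defs: PBDefinitions | None = None,
    geometry: BackboneGeometry = BackboneGeometry(),
) -> BackboneChain:
    """A chain built by tiling one PB's five-residue reference dihedrals.

    Every position whose window lands in phase with the tiling sees the
    exact reference vector and is guaranteed to re-encode to ``letter``.
    Off-phase windows mix shifted copies of the vector: for non-uniform
    (transition) blocks those windows legitimately encode to other letters,
    so only near-uniform prototypes such as the helix block ``m`` come back
    as an unbroken run.
    """
    frag = fragment_script(letter, defs)
    return build_backbone([frag[i % 5] for i in range(length)], geometry)


@dataclass(frozen=True)
class Edit:
    """One modification of the base chain over residues [start, end)."""

    kind: str  # rigid_rotate_loop | change_dihedrals | insert | delete | substitute_aa
    start: int
    end: int
    params: dict = field(default_factory=dict)

    KINDS = ("rigid_rotate_loop", "change_dihedrals", "insert", "delete", "substitute_aa")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "insert":
            if self.params.get("length", 0) < 1:
                raise ValueError("insert needs params['length'] >= 1")
        elif not self.start < self.end:
            raise ValueError("edit span must be non-empty")


@dataclass(frozen=True)
class PairRecipe:
    """Base dihedral script plus an ordered list of non-overlapping edits."""

    base: list  # [(phi, psi), ...]
    edits: tuple = ()
    name: str = "pair"

    def __post_init__(self):
        spans = sorted(
            (e.start, e.end if e.kind != "insert" else e.start) for e in self.edits
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("edit spans overlap")
        n = len(self.base)
        for e in self.edits:
            if e.start < 0 or (e.kind != "insert" and e.end > n) or e.start > n:
                raise ValueError("edit span out of range")
            if e.kind == "rigid_rotate_loop" and (e.start < 1 or e.end > n - 1):
                raise ValueError("rigid_rotate_loop needs hinge residues on both sides")


@dataclass
class PairGroundTruth:
    """What the pipeline is expected to find for a generated pair."""

    regions: list  # Region tiling of the induced alignment
    svr_classes: dict  # svr_id -> "similar" | "dissimilar" | None


def _rotate_span(chain: BackboneChain, start: int, end: int, angle_deg: float) -> list:
    """Rigidly rotate residues [start, end) about the hinge CA-CA axis."""
    p0 = chain[start - 1].CA
    p1 = chain[end].CA
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    moved = []
    for res in chain.residues[start:end]:
        moved.append(
            replace(
                res,
                N=rot.apply(res.N - p0) + p0,
                CA=rot.apply(res.CA - p0) + p0,
                C=rot.apply(res.C - p0) + p0,
            )
        )
    return moved


def _random_far_angles(rng, base_phi_psi, min_sep=60.0):
    """Draw (phi, psi) uniformly, at least min_sep degrees (wrapped) from base."""
    while True:
        phi = float(rng.uniform(-180.0, 180.0))
        psi = float(rng.uniform(-180.0, 180.0))
        dp = abs((phi - base_phi_psi[0] + 180.0) % 360.0 - 180.0)
        ds = abs((psi - base_phi_psi[1] + 180.0) % 360.0 - 180.0)
        if dp >= min_sep and ds >= min_sep:
            return phi, psi


def make_homolog_pair(
    recipe: PairRecipe,
    seed: int = 0,
    geometry: BackboneGeometry = BackboneGeometry(),
):
    """Build (chain_a, chain_b, alignment, ground_truth) from a recipe.

    chain A is the base script verbatim; chain B applies the edits.  The
    alignment is the trivial residue-index correspondence with gap columns
    inserted for indels.  Ground truth records the intended SVR spans (edit
    spans, in alignment columns) and the expected class where the edit kind
    implies one.
    """
    rng = np.random.default_rng(seed)
    base = [(float(p), float(s)) for p, s in recipe.base]
    n = len(base)
    chain_a = build_backbone(base, geometry, chain_id="A")

    # --- non-indel coordinate edits on a copy of A's residues -------------
    b_residues = list(chain_a.residues)
    for e in recipe.edits:
        if e.kind == "change_dihedrals":
            new_script = list(base)
            for i in range(e.start, e.end):
                if "phi" in e.params and "psi" in e.params:
                    new_script[i] = (float(e.params["phi"]), float(e.params["psi"]))
                else:
                    new_script[i] = _random_far_angles(rng, base[i])
            raw = build_backbone(new_script, geometry)
            # the rebuilt chain coincides with A up to the span's first CA,
            # so the fragment splices seamlessly onto the left hinge
            for i in range(e.start, e.end):
                b_residues[i] = replace(
                    b_residues[i], N=raw[i].N, CA=raw[i].CA, C=raw[i].C
                )
        elif e.kind == "rigid_rotate_loop":
            angle = float(e.params.get("angle", 150.0))
            moved = _rotate_span(chain_a, e.start, e.end, angle)
            b_residues[e.start : e.end] = moved
        elif e.kind == "substitute_aa":
            letters = e.params.get("letters")
            for k, i in enumerate(range(e.start, e.end)):
                aa = letters[k] if letters else "G"
                b_residues[i] = replace(b_residues[i], amino_acid=aa)

    # --- indels + alignment rows ------------------------------------------
    inserts = {e.start: e for e in recipe.edits if e.kind == "insert"}
    deleted = set()
    for e in recipe.edits:
        if e.kind == "delete":
            deleted.update(range(e.start, e.end))

    row_a, row_b, final_b = [], [], []
    col_of_base = {}  # base residue index -> alignment column
    insert_cols = {}  # insert position -> (col_start, col_end)
    col = 0
    for i in range(n + 1):
        if i in inserts:
            e = inserts[i]
            length = int(e.params["length"])
            phi = float(e.params.get("phi", -70.0))
            psi = float(e.params.get("psi", 140.0))
            ins_script = list(base[:i]) + [(phi, psi)] * length + list(base[i:])
            raw = build_backbone(ins_script, geometry)
            insert_cols[i] = (col, col + length)
            for k in range(length):
                row_a.append("-")
                row_b.append("A")
                final_b.append(
                    Residue(
                        residue_number=0, insertion_code="", amino_acid="A",
                        N=raw[i + k].N, CA=raw[i + k].CA, C=raw[i + k].C,
                    )
                )
                col += 1
        if i == n:
            break
        col_of_base[i] = col
        row_a.append(chain_a[i].amino_acid)
        if i in deleted:
            row_b.append("-")
        else:
            row_b.append(b_residues[i].amino_acid)
            final_b.append(b_residues[i])
        col += 1

    final_b = [
        replace(r, residue_number=k + 1) for k, r in enumerate(final_b)
    ]
    chain_b = BackboneChain(chain_id="B", residues=final_b)
    aln = PairwiseAlignment(row_a="".join(row_a), row_b="".join(row_b))

    # --- ground truth ------------------------------------------------------
    class_of_kind = {"rigid_rotate_loop": "similar", "change_dihedrals": "dissimilar"}
    svr_spans = []
    for e in recipe.edits:
        if e.kind == "substitute_aa":
            continue
        if e.kind == "insert":
            span = insert_cols[e.start]
        else:
            span = (col_of_base[e.start], col_of_base[e.end - 1] + 1)
        svr_spans.append((span, class_of_kind.get(e.kind)))
    svr_spans.sort()
    regions, classes = [], {}
    pos, svr_id = 0, 0
    for (s, t), cls in svr_spans:
        if s > pos:
            regions.append(Region(start=pos, end=s, kind="SCR"))
        svr_id += 1
        regions.append(
            Region(start=s, end=t, kind="SVR",
                   terminal=(s == 0 or t == aln.length), svr_id=svr_id)
        )
        classes[svr_id] = cls
        pos = t
    if pos < aln.length:
        regions.append(Region(start=pos, end=aln.length, kind="SCR"))
    truth = PairGroundTruth(regions=regions, svr_classes=classes)
    return chain_a, chain_b, aln, truth


# ---------------------------------------------------------------------------
# canned recipes used by the documentation, tests and acceptance checks
# ---------------------------------------------------------------------------

def demo_recipe(kind: str = "rigid_rotate_loop", defs: PBDefinitions | None = None) -> PairRecipe:
    """A 40-residue chain — extended flanks around a central helical loop
    (residues 16..24) — with one edit of the requested kind over the loop.

    ``rigid_rotate_loop`` swings the loop 150 degrees about its hinge axis
    (unchanged internal conformation, displaced by several angstroms);
    ``change_dihedrals`` deterministically rewrites the loop's backbone to
    the central dihedrals of a polyproline-like transition block, i.e. a
    genuinely different conformation.
    """
    if defs is None:
        defs = PBDefinitions.load()
    base = script_from_pbs("d" * 16 + "m" * 8 + "d" * 16, defs)
    if kind == "identity":
        return PairRecipe(base=base, edits=(), name="identity")
    if kind == "rigid_rotate_loop":
        edit = Edit(kind="rigid_rotate_loop", start=16, end=24, params={"angle": 150.0})
    elif kind == "change_dihedrals":
        phi, psi = defs.central_phi_psi("g")
        edit = Edit(kind="change_dihedrals", start=16, end=24,
                    params={"phi": phi, "psi": psi})
    else:
        raise ValueError(f"no demo recipe for kind {kind!r}")
    return PairRecipe(base=base, edits=(edit,), name=f"demo_{kind}")


def recipe_from_dict(d: dict, defs: PBDefinitions | None = None) -> PairRecipe:
    """Build a recipe from parsed structured config (e.g. YAML).

    ``base`` is either a PB string or a list of [phi, psi] pairs; each edit
    is a mapping with ``kind``, ``start``, ``end`` and optional parameters.
    """
    base = d["base"]
    if isinstance(base, str):
        base = script_from_pbs(base, defs)
    edits = tuple(
        Edit(
            kind=e["kind"], start=int(e["start"]), end=int(e.get("end", e["start"])),
            params={k: v for k, v in e.items() if k not in ("kind", "start", "end")},
        )
        for e in d.get("edits", [])
    )
    return PairRecipe(base=base, edits=edits, name=d.get("name", "pair"))
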