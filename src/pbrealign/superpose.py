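"""Rigid-body superposition, per-column CA distances, RMSD and SDM.

The least-squares fit is the closed-form proper-rotation (SVD/Kabsch)
solution: the optimum of the same objective the classic iterative
rigid-body matching algorithms converge to, computed deterministically.
Reflections are never returned — if the best orthogonal map is improper,
the smallest singular direction is flipped, which yields the optimal
proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, with a proper rotation matrix."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    def apply(self, coords) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def as_flat(self) -> np.ndarray:
        """12 numbers: row-major rotation then translation."""
        return np.concatenate([np.ravel(self.rotation), np.ravel(self.translation)])


def fit_superposition(
    coords_a, coords_b
) -> tuple[RigidTransform, float]:
    """Least-squares proper-rotation fit of B onto A.

    Returns the transform minimising sum ||R b + t - a||^2 and the minimised
    RMSD.  Requires at least 3 non-collinear points in each set.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    for label, M in (("A", A0), ("B", B0)):
        if np.linalg.matrix_rank(M, tol=1e-8) < 2:
            raise DegenerateGeometryError(f"points of set {label} are collinear")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    transform = RigidTransform(rotation=R, translation=t)
    rmsd = rmsd_fixed_frame(A, transform.apply(B))
    return transform, rmsd


def rmsd_fixed_frame(coords_a, coords_b) -> float:
    """Root mean square CA-CA deviation with NO refitting.

    Used for "before" values: distances are measured in whatever frame the
    coordinates already sit in.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.size == 0:
        raise ValueError("coordinate sets must be equal-length and non-empty")
    d2 = np.sum((A - B) ** 2, axis=-1)
    return float(np.sqrt(np.mean(d2)))


def column_distances(aln, chain_a, chain_b, transform: RigidTransform) -> np.ndarray:
    """Per-alignment-column CA-CA distance (A) after moving chain B.

    Gap columns are NaN.  The alignment provides column -> residue maps for
    both chains.
    """
    ca_a = chain_a.coords("CA")
    ca_b = transform.apply(chain_b.coords("CA"))
    out = np.full(aln.length, np.nan)
    for col in range(aln.length):
        ia, ib = aln.colmap_a[col], aln.colmap_b[col]
        if ia is None or ib is None:
            continue
        if ia >= len(ca_a) or ib >= len(ca_b):
            raise IndexError(f"column {col} maps outside a chain")
        out[col] = np.linalg.norm(ca_a[ia] - ca_b[ib])
    return out


def sdm(
    fragment_a,
    fragment_b,
    equivalences: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Structural distance metric: length-normalised RMSD-derived score.

    Default plug-in form is ``100 * rmsd / n_equivalences`` (the classic
    match-length normalisation of RMSD): zero for identical fragments,
    monotone in RMSD at fixed length, and smaller for longer fragments at
    equal RMSD.  RMSD is measured in the frame the fragments are given in;
    callers wanting an "after local refit" value transform the coordinates
    first.
    """
    A = np.asarray(fragment_a, dtype=float)
    B = np.asarray(fragment_b, dtype=float)
    if equivalences is None:
        if A.shape != B.shape:
            raise ValueError("implicit equivalences need equal-length fragments")
        equivalences = [(i, i) for i in range(A.shape[0])]
    if len(equivalences) == 0:
        raise ValueError("sdm needs at least one equivalenced pair")
    ia = [p[0] for p in equivalences]
    ib = [p[1] for p in equivalences]
    r = rmsd_fixed_frame(A[ia], B[ib])
    return 100.0 * r / len(equivalences)
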