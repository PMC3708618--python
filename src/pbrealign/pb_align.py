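"""Global dynamic-programming alignment of PB strings.

SVR realignment scores PB letter pairs with a 16x16 substitution matrix
(the structural-alphabet analogue of an amino-acid substitution matrix) and
an affine gap model, using standard Needleman-Wunsch/Gotoh recurrences with
a deterministic traceback.

The bundled default matrix, ``pb_substitution_synthetic.tsv``, is a
SYNTHETIC stand-in derived from the angular distances between the 16 PB
reference vectors: score(x, y) = 2 - 6 * rmsda(x, y) / max_rmsda, rounded
to 2 decimals.  It is symmetric with a dominant +2.0 diagonal and
increasingly negative scores for geometrically distant blocks, and can be
replaced by any empirically derived matrix in the same TSV layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .pb_codec import PB_ALPHABET, UNASSIGNED

_DEFAULT_MATRIX = "pb_substitution_synthetic.tsv"

GAP = "-"


@dataclass(frozen=True)
class PBSubstitutionMatrix:
    """Symmetric letter-pair scores over the PB alphabet.

    ``Z`` (unassigned) scores 0 against anything: it is absence of
    information, not a 17th state.
    """

    letters: str
    values: np.ndarray  # (16, 16)

    def __post_init__(self):
        if self.letters != PB_ALPHABET:
            raise ValueError("matrix alphabet must be a..p in order")
        if self.values.shape != (16, 16):
            raise ValueError("expected a 16x16 matrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (np.diag(self.values) >= self.values.max(axis=1) - 1e-12).all():
            raise ValueError("each diagonal entry must be its row's maximum")
        lookup = {}
        for i, a in enumerate(self.letters):
            lookup[(a, UNASSIGNED)] = lookup[(UNASSIGNED, a)] = 0.0
            for j, b in enumerate(self.letters):
                lookup[(a, b)] = float(self.values[i, j])
        lookup[(UNASSIGNED, UNASSIGNED)] = 0.0
        object.__setattr__(self, "_lookup", lookup)

    def score(self, x: str, y: str) -> float:
        try:
            return self._lookup[(x, y)]
        except KeyError:
            raise ValueError(f"letter pair ({x!r}, {y!r}) outside the PB alphabet")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PBSubstitutionMatrix":
        """Load a matrix TSV (header row of letters, then 16 labelled rows)."""
        if path is None:
            text = (resources.files("pbrealign.data") / _DEFAULT_MATRIX).read_text()
        else:
            text = Path(path).read_text()
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")[1:]
        letters = "".join(header)
        rows = []
        row_letters = []
        for ln in lines[1:]:
            parts = ln.split("\t")
            row_letters.append(parts[0])
            rows.append([float(v) for v in parts[1:17]])
        if letters != "".join(row_letters):
            raise ValueError("matrix row order disagrees with header order")
        return cls(letters=letters, values=np.array(rows))


@dataclass(frozen=True)
class GapModel:
    """Affine gaps: a run of k gap symbols costs gap_open + (k-1)*gap_extend."""

    gap_open: float = -5.0
    gap_extend: float = -0.5

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")


@dataclass(frozen=True)
class PBAlignmentResult:
    row_x: str
    row_y: str
    raw_score: float
    aligned_columns: int


def align_global(
    x: str, y: str, matrix: PBSubstitutionMatrix, gaps: GapModel = GapModel()
) -> PBAlignmentResult:
    """Optimal global affine-gap alignment of two ungapped PB strings.

    Traceback ties resolve deterministically in the order diagonal (match),
    up (gap in y), left (gap in x); within a gap state, closing the gap is
    preferred over extending it.
    """
    if not x or not y:
        raise ValueError("align_global requires two non-empty PB strings")
    for s in (x, y):
        for ch in s:
            if ch not in PB_ALPHABET and ch != UNASSIGNED:
                raise ValueError(f"unknown PB letter {ch!r}")
    n, m = len(x), len(y)
    go, ge = gaps.gap_open, gaps.gap_extend
    NEG = float("-inf")
    score = matrix.score
    # state 0 = M (x[i-1] ~ y[j-1]); 1 = IX, gap in y (x consumed); 2 = IY.
    # Plain-list DP: the matrices are tiny in the SVR use case but the
    # aligner is swept over very many string pairs in validation.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    IX = [[NEG] * (m + 1) for _ in range(n + 1)]
    IY = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[-1] * (m + 1) for _ in range(n + 1)]
    pX = [[-1] * (m + 1) for _ in range(n + 1)]
    pY = [[-1] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        IX[i][0] = go + (i - 1) * ge
        pX[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        IY[0][j] = go + (j - 1) * ge
        pY[0][j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        xi = x[i - 1]
        Mi, Mp = M[i], M[i - 1]
        Xi, Xp = IX[i], IX[i - 1]
        Yi, Yp = IY[i], IY[i - 1]
        for j in range(1, m + 1):
            # ties resolve in order M, IX, IY (diagonal, up, left)
            a, b, c = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            v, st = (a, 0)
            if b > v:
                v, st = b, 1
            if c > v:
                v, st = c, 2
            Mi[j] = v + score(xi, y[j - 1])
            pM[i][j] = st
            a, b, c = Mp[j] + go, Xp[j] + ge, Yp[j] + go
            v, st = (a, 0)
            if b > v:
                v, st = b, 1
            if c > v:
                v, st = c, 2
            Xi[j] = v
            pX[i][j] = st
            a, b, c = Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge
            v, st = (a, 0)
            if b > v:
                v, st = b, 1
            if c > v:
                v, st = c, 2
            Yi[j] = v
            pY[i][j] = st
    best, state = (M[n][m], 0)
    if IX[n][m] > best:
        best, state = IX[n][m], 1
    if IY[n][m] > best:
        best, state = IY[n][m], 2
    out_x: list[str] = []
    out_y: list[str] = []
    i, j = n, m
    ptrs = (pM, pX, pY)
    while i > 0 or j > 0:
        prev = ptrs[state][i][j]
        if state == 0:
            out_x.append(x[i - 1])
            out_y.append(y[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out_x.append(x[i - 1])
            out_y.append(GAP)
            i -= 1
        else:
            out_x.append(GAP)
            out_y.append(y[j - 1])
            j -= 1
        state = prev
    row_x = "".join(reversed(out_x))
    row_y = "".join(reversed(out_y))
    aligned = sum(
        1 for a, b in zip(row_x, row_y) if a != GAP and b != GAP
    )
    return PBAlignmentResult(
        row_x=row_x, row_y=row_y, raw_score=float(best), aligned_columns=aligned
    )


def pb_score(
    row_x: str, row_y: str, matrix: PBSubstitutionMatrix
) -> tuple[float, float | None]:
    """Raw and per-column PB score of a gapped PB row pair.

    Raw is the sum of substitution-matrix values over columns where both
    rows hold letters from a..p; normalised divides by the number of such
    columns (None when there are none).  Gap penalties and ``Z`` columns do
    not contribute.
    """
    if len(row_x) != len(row_y):
        raise ValueError("gapped PB rows must have equal length")
    raw = 0.0
    cols = 0
    for a, b in zip(row_x, row_y):
        if a in PB_ALPHABET and b in PB_ALPHABET:
            raw += matrix.score(a, b)
            cols += 1
    return raw, (raw / cols if cols else None)
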