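"""Partition alignment columns into SCRs and SVRs.

A column is SVR-candidate when its superposed CA-CA distance exceeds the
threshold (3 A by default) or when it is a gap column (no defined distance).
Maximal candidate runs of at least ``svr_min_len`` columns become SVRs;
shorter runs are absorbed into the surrounding SCR.  Runs touching either
end of the alignment are flagged terminal — the two unassigned PB positions
at each chain end make terminal SVRs unassessable, so they are excluded
from scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

SCR_MAX_DISTANCE = 3.0
SVR_MIN_LENGTH = 3


@dataclass(frozen=True)
class Region:
    """Half-open column interval [start, end) of one kind."""

    start: int
    end: int
    kind: str  # "SCR" | "SVR"
    terminal: bool = False
    svr_id: int | None = None
    excluded: bool = False

    def __len__(self) -> int:
        return self.end - self.start


def segment(
    distances,
    scr_max: float = SCR_MAX_DISTANCE,
    svr_min_len: int = SVR_MIN_LENGTH,
) -> list[Region]:
    """Segment per-column distances into an ordered SCR/SVR tiling.

    Parameters
    ----------
    distances : per-column CA-CA distance in A; NaN for gap columns.
    scr_max : columns with distance <= scr_max are conserved.
    svr_min_len : minimum run length for a variable region.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty 1-D array")
    candidate = np.isnan(d) | (d > scr_max)
    n = d.size
    # maximal candidate runs of sufficient length become SVRs
    is_svr = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            if j - i >= svr_min_len:
                is_svr[i:j] = True
            i = j
        else:
            i += 1
    regions: list[Region] = []
    svr_id = 0
    i = 0
    while i < n:
        j = i
        while j < n and is_svr[j] == is_svr[i]:
            j += 1
        if is_svr[i]:
            svr_id += 1
            regions.append(
                Region(start=i, end=j, kind="SVR",
                       terminal=(i == 0 or j == n), svr_id=svr_id)
            )
        else:
            regions.append(Region(start=i, end=j, kind="SCR"))
        i = j
    return regions


def exclude_terminal(regions: list[Region]) -> list[Region]:
    """Mark terminal SVRs as excluded from assessment (intervals retained)."""
    return [
        replace(r, excluded=True) if r.kind == "SVR" and r.terminal else r
        for r in regions
    ]


def svr_regions(regions: list[Region], include_excluded: bool = False) -> list[Region]:
    """The SVR intervals, by default only the assessable (non-excluded) ones."""
    return [
        r for r in regions
        if r.kind == "SVR" and (include_excluded or not r.excluded)
    ]
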