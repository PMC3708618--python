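"""Per-SVR realignment, before/after metrics and similarity classification.

For every assessable SVR the pipeline:

1. measures "before" metrics from the original column equivalences in the
   global superposition frame (RMSD, SDM);
2. excises both sides' PB subsequences (gaps and ``Z`` dropped, residue
   bookkeeping kept), realigns them globally with the PB substitution
   matrix and affine gaps;
3. measures "after" metrics on the realigned residue equivalences — RMSD
   after a LOCAL rigid refit of the SVR fragments (it is exactly this local
   refit that can reveal a loop with an unchanged conformation displaced by
   a rigid-body reorientation);
4. classifies the SVR as conformationally similar when the normalised
   (per-aligned-column) PB score is >= the cutoff (-0.42 by default,
   inclusive), dissimilar otherwise.

SVRs whose shorter PB subsequence has fewer than ``min_pbs`` letters (4 by
default, i.e. "more than three aligned PBs") are not assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


from .alignment_model import AnnotatedAlignment, PairwiseAlignment
from .pb_align import GAP, GapModel, PBAlignmentResult, PBSubstitutionMatrix, align_global, pb_score
from .pb_codec import PB_ALPHABET
from .segmentation import Region
from .superpose import RigidTransform, fit_superposition, rmsd_fixed_frame, sdm

log = logging.getLogger(__name__)

PB_SCORE_CUTOFF = -0.42
REALIGN_MIN_PBS = 4

CLASS_SIMILAR = "similar"
CLASS_DISSIMILAR = "dissimilar"
CLASS_NOT_ASSESSED = "not_assessed"


@dataclass
class SVRAssessment:
    """Scores and classification of one structurally variable region."""

    svr_id: int
    col_start: int
    col_end: int
    len_a: int
    len_b: int
    eligible: bool
    pb_score_raw: float | None
    pb_score_norm: float | None
    rmsd_before: float | None
    rmsd_after: float | None
    sdm_before: float | None
    sdm_after: float | None
    svr_class: str
    local_refit: bool = False
    realigned_a: str = ""
    realigned_b: str = ""


def extract_svr_pbs(
    pb_row_a: str, pb_row_b: str, aln: PairwiseAlignment, region: Region
) -> tuple[str, list[int], str, list[int]]:
    """Excise both sides' PB subsequences over an SVR's columns.

    Gap and ``Z`` symbols are dropped; for each kept letter the residue
    index (from the alignment's column map) is recorded so realigned PB
    columns can be mapped back to residue equivalences.
    """
    def one(row, colmap):
        letters, idx = [], []
        for col in range(region.start, region.end):
            ch = row[col]
            if ch in PB_ALPHABET:
                letters.append(ch)
                idx.append(colmap[col])
        return "".join(letters), idx

    pb_x, idx_x = one(pb_row_a, aln.colmap_a)
    pb_y, idx_y = one(pb_row_b, aln.colmap_b)
    return pb_x, idx_x, pb_y, idx_y


def is_eligible(pb_x: str, pb_y: str, min_pbs: int = REALIGN_MIN_PBS) -> bool:
    """Realignment eligibility: the shorter side must have >= min_pbs PBs."""
    return min(len(pb_x), len(pb_y)) >= min_pbs


def _equivalences_from_rows(
    row_x: str, row_y: str, idx_x: list[int], idx_y: list[int]
) -> list[tuple[int, int]]:
    """Letter-letter columns of a gapped PB row pair -> residue index pairs."""
    pairs = []
    i = j = 0
    for a, b in zip(row_x, row_y):
        if a != GAP and b != GAP:
            pairs.append((idx_x[i], idx_y[j]))
        if a != GAP:
            i += 1
        if b != GAP:
            j += 1
    return pairs


def assess_svr(
    chain_a,
    chain_b,
    region: Region,
    aln: PairwiseAlignment,
    pb_row_a: str,
    pb_row_b: str,
    matrix: PBSubstitutionMatrix,
    gaps: GapModel = GapModel(),
    cutoff: float = PB_SCORE_CUTOFF,
    min_pbs: int = REALIGN_MIN_PBS,
    global_transform: RigidTransform | None = None,
    sdm_metric=sdm,
) -> SVRAssessment:
    """Assess one non-terminal SVR; see the module docstring for the steps."""
    if region.kind != "SVR":
        raise ValueError("assess_svr expects an SVR region")
    if global_transform is None:
        global_transform = RigidTransform.identity()
    ca_a = chain_a.coords("CA")
    ca_b_global = global_transform.apply(chain_b.coords("CA"))

    len_a = sum(1 for c in range(region.start, region.end) if aln.colmap_a[c] is not None)
    len_b = sum(1 for c in range(region.start, region.end) if aln.colmap_b[c] is not None)

    # "before": original column equivalences, global frame
    before_pairs = [
        (aln.colmap_a[c], aln.colmap_b[c])
        for c in range(region.start, region.end)
        if aln.colmap_a[c] is not None and aln.colmap_b[c] is not None
    ]
    rmsd_before = sdm_before = None
    if before_pairs:
        ia = [p[0] for p in before_pairs]
        ib = [p[1] for p in before_pairs]
        rmsd_before = rmsd_fixed_frame(ca_a[ia], ca_b_global[ib])
        sdm_before = sdm_metric(ca_a, ca_b_global, before_pairs)

    pb_x, idx_x, pb_y, idx_y = extract_svr_pbs(pb_row_a, pb_row_b, aln, region)
    eligible = is_eligible(pb_x, pb_y, min_pbs)
    result = SVRAssessment(
        svr_id=region.svr_id or 0,
        col_start=region.start,
        col_end=region.end,
        len_a=len_a,
        len_b=len_b,
        eligible=eligible,
        pb_score_raw=None,
        pb_score_norm=None,
        rmsd_before=rmsd_before,
        rmsd_after=None,
        sdm_before=sdm_before,
        sdm_after=None,
        svr_class=CLASS_NOT_ASSESSED,
    )
    if not eligible:
        return result

    realigned: PBAlignmentResult = align_global(pb_x, pb_y, matrix, gaps)
    raw, norm = pb_score(realigned.row_x, realigned.row_y, matrix)
    result.pb_score_raw = raw
    result.pb_score_norm = norm
    result.realigned_a = realigned.row_x
    result.realigned_b = realigned.row_y
    if norm is not None:
        result.svr_class = CLASS_SIMILAR if norm >= cutoff else CLASS_DISSIMILAR
    else:
        # realignment found no letter-letter column at all: there is no
        # local similarity to speak of, so the region is dissimilar
        result.svr_class = CLASS_DISSIMILAR

    after_pairs = _equivalences_from_rows(realigned.row_x, realigned.row_y, idx_x, idx_y)
    if after_pairs:
        ia = [p[0] for p in after_pairs]
        ib = [p[1] for p in after_pairs]
        frag_a = ca_a[ia]
        frag_b = chain_b.coords("CA")[ib]
        if len(after_pairs) >= 3:
            try:
                local, rmsd_local = fit_superposition(frag_a, frag_b)
                result.rmsd_after = rmsd_local
                result.local_refit = True
                result.sdm_after = sdm_metric(
                    frag_a, local.apply(frag_b),
                    [(k, k) for k in range(len(after_pairs))],
                )
            except Exception:  # collinear fragments: fall back to global frame
                result.local_refit = False
        if not result.local_refit:
            # too few (or degenerate) equivalences for a local fit: report in
            # the global superposition frame and flag it
            gb = ca_b_global[ib]
            result.rmsd_after = rmsd_fixed_frame(frag_a, gb)
            result.sdm_after = sdm_metric(
                frag_a, gb, [(k, k) for k in range(len(after_pairs))]
            )
    return result


def merge_results(
    aln: PairwiseAlignment,
    regions: list[Region],
    assessments: list[SVRAssessment],
    pb_row_a: str,
    pb_row_b: str,
) -> AnnotatedAlignment:
    """Combine segmentation and per-SVR assessments into column labels.

    Every non-excluded SVR must carry an assessment; excluded (terminal) and
    unassessed SVRs are labelled ``SVR_excluded``.
    """
    by_id = {a.svr_id: a for a in assessments}
    labels = ["SCR"] * aln.length
    for region in regions:
        if region.kind != "SVR":
            continue
        if region.excluded:
            label = "SVR_excluded"
        else:
            a = by_id.get(region.svr_id)
            if a is None:
                raise ValueError(f"missing assessment for SVR {region.svr_id}")
            label = {
                CLASS_SIMILAR: "SVR_similar",
                CLASS_DISSIMILAR: "SVR_dissimilar",
                CLASS_NOT_ASSESSED: "SVR_excluded",
            }[a.svr_class]
        for c in range(region.start, region.end):
            labels[c] = label
    return AnnotatedAlignment(
        alignment=aln,
        labels=labels,
        pb_row_a=pb_row_a,
        pb_row_b=pb_row_b,
        regions=regions,
        assessments=assessments,
    )
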