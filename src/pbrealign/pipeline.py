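"""End-to-end pair-level pipeline.

read structures -> encode PBs -> superpose -> per-column distances ->
SCR/SVR segmentation -> terminal exclusion -> per-SVR realignment and
scoring -> annotated alignment + assessment TSV + superposed coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import alignment_model, assess, segmentation
from .alignment_model import AnnotatedAlignment, PairwiseAlignment, project_pbs, read_pair_fasta
from .config import PipelineConfig
from .errors import SequenceMismatchError
from .pb_align import GapModel, PBSubstitutionMatrix
from .pb_codec import PBDefinitions, encode_chain
from .structure_io import BackboneChain, read_backbone, write_superposed
from .superpose import RigidTransform, column_distances, fit_superposition

log = logging.getLogger(__name__)


@dataclass
class PairResult:
    annotated: AnnotatedAlignment
    transform: RigidTransform
    distances: np.ndarray
    pb_a: str
    pb_b: str


def _check_alignment_matches(aln: PairwiseAlignment, chain_a: BackboneChain, chain_b: BackboneChain) -> None:
    for name, ungapped, chain in (
        ("A", aln.ungapped_a(), chain_a),
        ("B", aln.ungapped_b(), chain_b),
    ):
        seq = chain.sequence.upper()
        if ungapped != seq:
            diffs = [
                f"  pos {i}: alignment {x!r} vs chain {y!r}"
                for i, (x, y) in enumerate(zip(ungapped, seq))
                if x != y
            ][:20]
            if len(ungapped) != len(seq):
                diffs.append(f"  lengths: alignment {len(ungapped)} vs chain {len(seq)}")
            raise SequenceMismatchError(
                f"alignment row {name} does not match chain {chain.chain_id!r} "
                f"sequence:\n" + "\n".join(diffs)
            )


def _aligned_ca(aln, chain_a, chain_b, columns=None):
    pairs = [
        (aln.colmap_a[c], aln.colmap_b[c])
        for c in (columns if columns is not None else range(aln.length))
        if aln.colmap_a[c] is not None and aln.colmap_b[c] is not None
    ]
    ca_a = chain_a.coords("CA")
    ca_b = chain_b.coords("CA")
    return ca_a[[p[0] for p in pairs]], ca_b[[p[1] for p in pairs]]


def run_pair_objects(
    chain_a: BackboneChain,
    chain_b: BackboneChain,
    aln: PairwiseAlignment,
    config: PipelineConfig = PipelineConfig(),
) -> PairResult:
    """Run the full method on in-memory objects; the library-level core of
    :func:`run_pair`."""
    _check_alignment_matches(aln, chain_a, chain_b)
    defs = PBDefinitions.load(config.pb_definitions)
    matrix = PBSubstitutionMatrix.load(config.substitution_matrix)
    gaps = GapModel(gap_open=config.gap_open, gap_extend=config.gap_extend)

    pb_a = encode_chain(chain_a, defs)
    pb_b = encode_chain(chain_b, defs)
    pb_row_a, pb_row_b = project_pbs(aln, pb_a, pb_b)

    coords_a, coords_b = _aligned_ca(aln, chain_a, chain_b)
    transform, global_rmsd = fit_superposition(coords_a, coords_b)
    log.info("global superposition over %d aligned columns: RMSD %.3f A",
             len(coords_a), global_rmsd)
    distances = column_distances(aln, chain_a, chain_b, transform)
    regions = segmentation.segment(distances, config.scr_max_dist, config.svr_min_len)

    if config.fit_on == "scr_iterative":
        scr_cols = [
            c for r in regions if r.kind == "SCR" for c in range(r.start, r.end)
        ]
        ca, cb = _aligned_ca(aln, chain_a, chain_b, scr_cols)
        if len(ca) >= 3:
            transform, scr_rmsd = fit_superposition(ca, cb)
            log.info("SCR-only refit over %d columns: RMSD %.3f A", len(ca), scr_rmsd)
            distances = column_distances(aln, chain_a, chain_b, transform)
            regions = segmentation.segment(
                distances, config.scr_max_dist, config.svr_min_len
            )

    regions = segmentation.exclude_terminal(regions)
    for r in regions:
        if r.kind == "SVR" and r.excluded:
            log.info("SVR %s at columns [%d, %d) is terminal: excluded", r.svr_id, r.start, r.end)

    assessments = [
        assess.assess_svr(
            chain_a, chain_b, region, aln, pb_row_a, pb_row_b, matrix, gaps,
            cutoff=config.pb_score_cutoff, min_pbs=config.realign_min_pbs,
            global_transform=transform,
        )
        for region in segmentation.svr_regions(regions)
    ]
    annotated = assess.merge_results(aln, regions, assessments, pb_row_a, pb_row_b)
    return PairResult(
        annotated=annotated, transform=transform, distances=distances,
        pb_a=pb_a, pb_b=pb_b,
    )


def run_pair(
    structure_a: str | Path,
    chain_a_id: str,
    structure_b: str | Path,
    chain_b_id: str,
    alignment_path: str | Path | None,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path = ".",
    prefix: str = "pair",
) -> dict:
    """File-level pipeline; returns the paths of the three outputs.

    When ``alignment_path`` is None an identity (residue-index) alignment is
    used, which requires equal-length chains — a convenience for toy pairs.
    """
    for key, value in config.to_dict().items():
        log.info("config %s = %r", key, value)
    chain_a = read_backbone(structure_a, chain_a_id)
    chain_b = read_backbone(structure_b, chain_b_id)
    if alignment_path is None:
        aln = PairwiseAlignment.identity(chain_a.sequence, chain_b.sequence)
    else:
        aln = read_pair_fasta(alignment_path)
    result = run_pair_objects(chain_a, chain_b, aln, config)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotated": outdir / f"{prefix}.annotated.txt",
        "svr_tsv": outdir / f"{prefix}.svr.tsv",
        "superposed": outdir / f"{prefix}.superposed.pdb",
    }
    alignment_model.write_annotated(result.annotated, paths["annotated"])
    write_assessment_tsv(result.annotated.assessments, paths["svr_tsv"])
    write_superposed(chain_a, chain_b, result.transform, paths["superposed"])
    log.info("wrote %s, %s, %s", *paths.values())
    return {"result": result, **paths}


def write_assessment_tsv(assessments, path: str | Path) -> None:
    lines = [alignment_model.SVR_HEADER]
    fmt = alignment_model._fmt
    for a in assessments:
        lines.append(
            "\t".join(
                [
                    str(a.svr_id), str(a.col_start), str(a.col_end),
                    str(a.len_a), str(a.len_b), str(int(a.eligible)),
                    fmt(a.pb_score_raw), fmt(a.pb_score_norm),
                    fmt(a.rmsd_before), fmt(a.rmsd_after),
                    fmt(a.sdm_before), fmt(a.sdm_after),
                    a.svr_class, str(int(a.local_refit)),
                    a.realigned_a or "", a.realigned_b or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_encode(
    structure: str | Path,
    chain_id: str,
    config: PipelineConfig = PipelineConfig(),
    out: str | Path | None = None,
) -> str:
    """Encode one chain as a PB string; optionally write single-record FASTA."""
    chain = read_backbone(structure, chain_id)
    defs = PBDefinitions.load(config.pb_definitions)
    pb = encode_chain(chain, defs)
    if out is not None:
        name = Path(str(structure)).stem
        Path(out).write_text(f">{name}_{chain_id} PB sequence\n{pb}\n")
    return pb
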