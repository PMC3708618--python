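"""Pairwise structure-based sequence alignments and their annotated form.

The toolkit consumes a pre-existing pairwise structure-based sequence
alignment (two aligned FASTA records) and produces an annotated flat file:
amino-acid rows with structurally conserved regions (SCRs) in uppercase and
structurally variable regions (SVRs) in lowercase, the projected PB rows,
a region line (``=`` SCR, ``s`` similar SVR, ``d`` dissimilar SVR, ``x``
SVR excluded from assessment), and a footer of per-SVR score records —
a plain-text stand-in for the blue/green/red colouring of the original
web display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import AlignmentFormatError

GAP = "-"

#: region-line symbol per column label
LABEL_SYMBOLS = {
    "SCR": "=",
    "SVR_similar": "s",
    "SVR_dissimilar": "d",
    "SVR_excluded": "x",
}
SYMBOL_LABELS = {v: k for k, v in LABEL_SYMBOLS.items()}

BLOCK_WIDTH = 60


def _colmap(row: str) -> tuple:
    out = []
    i = 0
    for ch in row:
        if ch == GAP:
            out.append(None)
        else:
            out.append(i)
            i += 1
    return tuple(out)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length plus column -> residue-index maps."""

    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise AlignmentFormatError(
                f"rows differ in length ({len(self.row_a)} vs {len(self.row_b)})"
            )
        if len(self.row_a) == 0:
            raise AlignmentFormatError("empty alignment")
        for col, (a, b) in enumerate(zip(self.row_a, self.row_b)):
            if a == GAP and b == GAP:
                raise AlignmentFormatError(f"column {col} is gap in both rows")

    @property
    def length(self) -> int:
        return len(self.row_a)

    @property
    def colmap_a(self) -> tuple:
        return _colmap(self.row_a)

    @property
    def colmap_b(self) -> tuple:
        return _colmap(self.row_b)

    def ungapped_a(self) -> str:
        return self.row_a.replace(GAP, "")

    def ungapped_b(self) -> str:
        return self.row_b.replace(GAP, "")

    @classmethod
    def identity(cls, sequence_a: str, sequence_b: str) -> "PairwiseAlignment":
        """Trivial residue-index alignment for equal-length chains."""
        if len(sequence_a) != len(sequence_b):
            raise AlignmentFormatError(
                "identity alignment needs equal-length sequences"
            )
        return cls(row_a=sequence_a.upper(), row_b=sequence_b.upper())


def read_pair_fasta(path: str | Path) -> PairwiseAlignment:
    """Read a two-record aligned FASTA.

    Both ``-`` and ``.`` are accepted as gaps and normalised to ``-``;
    residue case in the input is ignored (case is an output annotation
    channel here).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise AlignmentFormatError(
            f"{path}: expected exactly 2 aligned records, found {len(records)}"
        )
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    return PairwiseAlignment(row_a=rows[0], row_b=rows[1])


def project_pbs(aln: PairwiseAlignment, pb_a: str, pb_b: str) -> tuple[str, str]:
    """Thread ungapped PB strings through the alignment's gap structure."""
    for name, pb, ungapped in (
        ("A", pb_a, aln.ungapped_a()),
        ("B", pb_b, aln.ungapped_b()),
    ):
        if len(pb) != len(ungapped):
            raise ValueError(
                f"PB sequence for chain {name} has length {len(pb)}, "
                f"chain has {len(ungapped)} residues"
            )
    row_pb_a = "".join(
        GAP if i is None else pb_a[i] for i in aln.colmap_a
    )
    row_pb_b = "".join(
        GAP if i is None else pb_b[i] for i in aln.colmap_b
    )
    return row_pb_a, row_pb_b


@dataclass
class AnnotatedAlignment:
    """A pairwise alignment plus per-column region labels, projected PB rows
    and per-SVR assessments (realigned PB row pairs live on the assessments
    because realignment can change an SVR's width)."""

    alignment: PairwiseAlignment
    labels: list  # per column, keys of LABEL_SYMBOLS
    pb_row_a: str
    pb_row_b: str
    regions: list = field(default_factory=list)  # segmentation.Region items
    assessments: list = field(default_factory=list)  # assess.SVRAssessment items

    def __post_init__(self):
        n = self.alignment.length
        if len(self.labels) != n or len(self.pb_row_a) != n or len(self.pb_row_b) != n:
            raise ValueError("labels and PB rows must match the alignment length")

    def region_line(self) -> str:
        return "".join(LABEL_SYMBOLS[label] for label in self.labels)

    def cased_rows(self) -> tuple[str, str]:
        """Amino-acid rows with SCR columns uppercase, SVR columns lowercase."""
        def case(row):
            return "".join(
                ch if label == "SCR" else ch.lower()
                for ch, label in zip(row, self.labels)
            )
        return case(self.alignment.row_a), case(self.alignment.row_b)


def _fmt(x, nd=4) -> str:
    if x is None:
        return "NA"
    try:
        import math
        if math.isnan(x):
            return "NA"
    except TypeError:
        pass
    return f"{x:.{nd}f}"


def _parse_float(s: str):
    return None if s == "NA" else float(s)


SVR_HEADER = (
    "svr_id\tcol_start\tcol_end\tlen_a\tlen_b\teligible\tpb_score_raw\t"
    "pb_score_norm\trmsd_before\trmsd_after\tsdm_before\tsdm_after\tclass\t"
    "local_refit\trealigned_a\trealigned_b"
)


def write_annotated(annotated: AnnotatedAlignment, path: str | Path) -> None:
    """Write the annotated flat file (blocks of 60 columns + TSV footers)."""
    aln = annotated.alignment
    aa_a, aa_b = annotated.cased_rows()
    rgn = annotated.region_line()
    lines = ["# pbrealign annotated alignment v1"]
    for start in range(0, aln.length, BLOCK_WIDTH):
        end = min(start + BLOCK_WIDTH, aln.length)
        lines.append(f"@block {start}")
        lines.append(f"AA_A {aa_a[start:end]}")
        lines.append(f"PB_A {annotated.pb_row_a[start:end]}")
        lines.append(f"PB_B {annotated.pb_row_b[start:end]}")
        lines.append(f"AA_B {aa_b[start:end]}")
        lines.append(f"RGN  {rgn[start:end]}")
    lines.append("@regions")
    lines.append("kind\tstart\tend\tterminal\tsvr_id\texcluded")
    for r in annotated.regions:
        lines.append(
            f"{r.kind}\t{r.start}\t{r.end}\t{int(r.terminal)}\t"
            f"{'' if r.svr_id is None else r.svr_id}\t{int(r.excluded)}"
        )
    lines.append("@svrs")
    lines.append(SVR_HEADER)
    for a in annotated.assessments:
        lines.append(
            "\t".join(
                [
                    str(a.svr_id),
                    str(a.col_start),
                    str(a.col_end),
                    str(a.len_a),
                    str(a.len_b),
                    str(int(a.eligible)),
                    _fmt(a.pb_score_raw),
                    _fmt(a.pb_score_norm),
                    _fmt(a.rmsd_before),
                    _fmt(a.rmsd_after),
                    _fmt(a.sdm_before),
                    _fmt(a.sdm_after),
                    a.svr_class,
                    str(int(a.local_refit)),
                    a.realigned_a or "",
                    a.realigned_b or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotated(path: str | Path) -> AnnotatedAlignment:
    """Parse a file written by :func:`write_annotated` (round-trip safe for
    rows, labels, regions and score records at written precision)."""
    from .assess import SVRAssessment  # local import avoids a cycle
    from .segmentation import Region

    aa_a = aa_b = pb_a = pb_b = rgn = ""
    regions: list = []
    assessments: list = []
    section = "blocks"
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        if line.startswith("@block"):
            continue
        if line == "@regions":
            section = "regions"
            continue
        if line == "@svrs":
            section = "svrs"
            continue
        if section == "blocks":
            tag, payload = line[:4].strip(), line[5:]
            if tag == "AA_A":
                aa_a += payload
            elif tag == "PB_A":
                pb_a += payload
            elif tag == "PB_B":
                pb_b += payload
            elif tag == "AA_B":
                aa_b += payload
            elif tag == "RGN":
                rgn += payload
        elif section == "regions":
            if line.startswith("kind\t"):
                continue
            kind, start, end, terminal, svr_id, excluded = line.split("\t")
            regions.append(
                Region(
                    start=int(start), end=int(end), kind=kind,
                    terminal=bool(int(terminal)),
                    svr_id=int(svr_id) if svr_id else None,
                    excluded=bool(int(excluded)),
                )
            )
        else:
            if line.startswith("svr_id\t"):
                continue
            f = line.split("\t")
            assessments.append(
                SVRAssessment(
                    svr_id=int(f[0]), col_start=int(f[1]), col_end=int(f[2]),
                    len_a=int(f[3]), len_b=int(f[4]), eligible=bool(int(f[5])),
                    pb_score_raw=_parse_float(f[6]), pb_score_norm=_parse_float(f[7]),
                    rmsd_before=_parse_float(f[8]), rmsd_after=_parse_float(f[9]),
                    sdm_before=_parse_float(f[10]), sdm_after=_parse_float(f[11]),
                    svr_class=f[12], local_refit=bool(int(f[13])),
                    realigned_a=f[14] if len(f) > 14 else "",
                    realigned_b=f[15] if len(f) > 15 else "",
                )
            )
    labels = [SYMBOL_LABELS[ch] for ch in rgn]
    aln = PairwiseAlignment(row_a=aa_a.upper(), row_b=aa_b.upper())
    return AnnotatedAlignment(
        alignment=aln, labels=labels, pb_row_a=pb_a, pb_row_b=pb_b,
        regions=regions, assessments=assessments,
    )
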