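# Methods

## The procedure

Given two homologous backbones A and B and a pairwise structure-based
sequence alignment of their chains, the pipeline:

1. reads each chain's N/Cα/C backbone (residues missing any of the three
   atoms are dropped with a warning; HETATM excluded; alternate locations
   resolve to the highest-occupancy conformer);
2. computes φ/ψ (φ<sub>i</sub> from C<sub>i−1</sub>–N<sub>i</sub>–Cα<sub>i</sub>–C<sub>i</sub>,
   ψ<sub>i</sub> from N<sub>i</sub>–Cα<sub>i</sub>–C<sub>i</sub>–N<sub>i+1</sub>,
   IUPAC sign convention) and encodes each chain as a Protein Block string:
   at every position with a complete eight-dihedral window, the letter
   minimising RMSDA = sqrt(mean of squared wrapped angular differences)
   against the 16 reference vectors, ties broken alphabetically; elsewhere
   the sentinel `Z`;
3. superposes B onto A by closed-form proper-rotation least squares over
   the aligned Cα pairs, measures per-column Cα–Cα distances, and segments
   the columns: distance ≤ 3 Å → conserved (SCR); maximal runs of ≥ 3
   columns with distance > 3 Å or gaps → variable (SVR); shorter
   excursions are absorbed into the SCR; runs touching either alignment
   end are flagged terminal and excluded from assessment;
4. for each assessable SVR, excises both sides' PB subsequences (gaps and
   `Z` dropped), realigns them by global affine-gap dynamic programming
   with the PB substitution matrix, and classifies the SVR as
   conformationally **similar** iff the normalised PB score — the mean
   substitution value over letter–letter columns of the realignment — is
   ≥ −0.42 (inclusive), **dissimilar** otherwise;
5. reports RMSD and SDM before realignment (original column equivalences,
   global superposition frame) and after (realigned equivalences, local
   rigid refit of the SVR fragments), and writes the annotated alignment,
   a per-SVR TSV and the superposed coordinates.

The local refit in step 5 is the operative trick: a loop with unchanged
internal conformation but a different rigid-body orientation has a large
"before" RMSD and a near-zero "after" RMSD, while a genuinely different
conformation stays bad in any frame and scores below the PB cutoff.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `scr_max_dist` | 3.0 | Å | max superposed Cα–Cα distance for a conserved column |
| `svr_min_len` | 3 | columns | minimum run length for a variable region |
| `realign_min_pbs` | 4 | letters | minimum PB count on the *shorter* side for realignment ("more than three") |
| `pb_score_cutoff` | −0.42 | per column | similar/dissimilar boundary, inclusive on the similar side |
| `gap_open`, `gap_extend` | −5.0, −0.5 | score | affine gaps: a run of k gap symbols costs open + (k−1)·extend |
| `fit_on` | `all` | — | superposition columns: all aligned columns, or `scr_iterative` (fit → segment → refit on SCR columns → resegment once) |

3 Å, ≥ 3 columns, > 3 aligned PBs and −0.42 are the method's published
operating point; the gap penalties are not published, so they are explicit
configuration with conventional defaults. The −0.42 cutoff is applied to
the **normalised** (per-aligned-column) score: a single fixed cutoff is
only meaningful across SVRs of widely varying lengths on a per-column
scale. Both the eligibility threshold and the side rule (shorter side vs
both) are configurable since the published phrasing is ambiguous; the
default reads "more than three aligned PBs" as ≥ 4 on the shorter side.
If a realignment yields no letter–letter column at all, the region is
classified dissimilar: there is no local similarity to report.

## Data assets and their provenance

* `data/pb_reference_angles.tsv` — the 16 PB reference vectors of the
  standard structural alphabet, transcribed from the published prototype
  table; overridable by flag.
* `data/pb_substitution_synthetic.tsv` — a **synthetic** substitution
  matrix. The empirically derived PB substitution matrices in the
  literature are not redistributable here, so the bundled default is
  constructed from the alphabet's own geometry:
  score(x, y) = 2 − 6·rmsda(x, y)/max<sub>uv</sub> rmsda(u, v), rounded to
  two decimals. It is symmetric, has a dominant +2.0 diagonal, a mean
  off-diagonal of ≈ −2.2, and scores geometrically close blocks (e.g.
  helix neighbours) mildly and distant ones strongly negative. It
  reproduces the method's qualitative behaviour; for production use,
  substitute an empirically derived matrix (same TSV layout) via
  configuration.

## SDM

The structural distance metric is a pluggable callable; the default is the
match-length-normalised RMSD, SDM = 100·RMSD/N<sub>aligned</sub>. It is 0
for identical fragments, monotone in RMSD at fixed length and decreasing
in length at fixed RMSD, which is the contract the pipeline relies on; the
exact published functional form differs but is not recoverable from the
values this package needs to reproduce.

## The synthetic generator

Chains are built from per-residue (φ, ψ) scripts by sequential
internal-coordinate (NeRF) placement with idealised trans-peptide geometry
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles 121.7°/111.2°/116.2°;
ω = 180°). Recomputing dihedrals on a built chain recovers the script to
10⁻⁶ degrees, making the builder the exact inverse of the encoder and the
whole pipeline testable against constructed truth.

Homolog pairs derive from a base script plus edits:

* `rigid_rotate_loop` rotates a span's atoms about the axis through its
  two hinge Cα atoms (which therefore stay fixed). The span's interior
  dihedrals — hence its interior PB letters — are untouched; only the two
  hinge residues' dihedrals change. This reproduces the phenomenon the
  method targets: a conformationally similar loop that is unsuperposable
  in the global frame. The demo scenario (40 residues, extended flanks,
  8-residue helical loop, 150° swing) displaces the loop by up to ≈ 6.4 Å.
* `change_dihedrals` rebuilds the span from rewritten (φ, ψ) (explicit,
  or drawn ≥ 60° from the base values) and splices the fragment onto the
  left hinge seamlessly; the right junction may break, which the encoder
  handles as a chain break (unassigned positions). This is a genuinely
  different conformation.
* `insert` / `delete` produce gap-bearing alignments; `substitute_aa`
  changes sequence only.

Ground truth records the intended SVR spans and classes. Hinge residues
blur region edges by construction, so span recovery is asserted to ± 2
columns.

What the generator does **not** emulate: real side chains, thermal
coordinate noise, experimental artefacts (missing atoms appear only in
hand-written test fixtures), non-trivial structure-based alignments (its
alignments are residue-index maps with indel gaps), or realistic
Ramachandran variation — scripts are idealised. Passing tests therefore
demonstrate the correctness of the machinery and the recoverability of
clean signals, not robustness to experimental noise.

## Numerical choices and degenerate inputs

* Superposition uses the closed-form SVD solution with the determinant
  correction, so reflections are never returned; it is the deterministic
  optimum of the same least-squares objective iterative rigid-body
  matchers converge to. Fewer than 3 points or collinear point sets are
  errors; an SVR whose realigned equivalence set is < 3 pairs (or
  collinear) skips the local refit and reports the global-frame RMSD with
  a flag.
* The all-column fit is a least-squares estimate and therefore
  outlier-sensitive: a large loop displacement tilts the global frame and
  can push conserved columns past 3 Å. The `scr_iterative` mode exists for
  exactly this case and re-fits on conserved columns once.
* DP traceback ties resolve deterministically (diagonal, then gap-in-B,
  then gap-in-A; closing a gap preferred over extending). `Z` scores 0
  against everything — absence of information, not a 17th letter.
* Chain breaks are declared at Cα–Cα > 4.5 Å; dihedrals spanning a break
  are undefined and their windows unassigned.
* Angles live in (−180°, 180°]; wrapped differences in [0°, 180°].
* Output numbers are fixed-format (4 decimals in TSVs, 3 in PDB
  coordinates), so identical inputs give byte-identical outputs.

## Known limitations

* A run of one PB letter is only geometrically self-consistent for
  near-uniform reference vectors (the helix prototype `m`, approximately
  the extended prototype `d`): consecutive assignment windows share six of
  eight dihedrals, so tiling a *transition* block's reference dihedrals
  legitimately encodes to other letters at off-phase positions. Encoder
  validation therefore checks exact-window recovery for all 16 letters and
  full-run recovery only where a run is realisable.
* The bundled substitution matrix is geometry-derived, not
  evolution-derived (above); absolute score values are not comparable to
  published PB scores, though the −0.42 operating point behaves correctly
  for clearly similar (positive means) and clearly dissimilar (strongly
  negative means) regions.
* The pipeline consumes a pre-existing structure-based alignment; it does
  not compute one (an identity alignment is accepted for equal-length toy
  pairs).
* Multi-chain assemblies, NMR ensembles beyond a model index, and
  family-level (multi-structure) consensus regions are out of scope.
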