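"""Synthetic backbone builder and homolog-pair generator."""

import numpy as np
import pytest

from pbrealign.config import PipelineConfig
from pbrealign.pb_codec import compute_dihedrals, encode_chain
from pbrealign.pipeline import run_pair_objects
from pbrealign.synthetic import (
    BackboneGeometry,
    Edit,
    PairRecipe,
    build_backbone,
    demo_recipe,
    make_homolog_pair,
    recipe_from_dict,
    script_from_pbs,
)


class TestBuildBackbone:
    def test_dihedral_round_trip(self):
        rng = np.random.default_rng(4)
        script = [tuple(rng.uniform(-170, 170, 2)) for _ in range(15)]
        chain = build_backbone(script)
        d = compute_dihedrals(chain)
        for i in range(1, 15):
            assert d.phi[i] == pytest.approx(script[i][0], abs=1e-6)
        for i in range(14):
            assert d.psi[i] == pytest.approx(script[i][1], abs=1e-6)

    def test_bond_lengths_match_geometry(self):
        g = BackboneGeometry()
        chain = build_backbone([(-57.0, -47.0)] * 10, g)
        for r in chain.residues:
            assert np.linalg.norm(r.CA - r.N) == pytest.approx(g.n_ca, abs=1e-9)
            assert np.linalg.norm(r.C - r.CA) == pytest.approx(g.ca_c, abs=1e-9)
        for r1, r2 in zip(chain.residues, chain.residues[1:]):
            assert np.linalg.norm(r2.N - r1.C) == pytest.approx(g.c_n, abs=1e-9)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BackboneGeometry(n_ca=2.5)
        with pytest.raises(ValueError):
            BackboneGeometry(angle_n_ca_c=85.0)
        with pytest.raises(ValueError):
            build_backbone([(-57.0, -47.0)])


class TestRecipes:
    def test_overlapping_edits_rejected(self):
        base = script_from_pbs("d" * 20)
        with pytest.raises(ValueError):
            PairRecipe(base=base, edits=(
                Edit(kind="delete", start=4, end=10),
                Edit(kind="delete", start=8, end=12),
            ))

    def test_out_of_range_edit_rejected(self):
        base = script_from_pbs("d" * 10)
        with pytest.raises(ValueError):
            PairRecipe(base=base, edits=(Edit(kind="delete", start=4, end=15),))
        with pytest.raises(ValueError):
            PairRecipe(base=base, edits=(
                Edit(kind="rigid_rotate_loop", start=0, end=5, params={"angle": 90.0}),
            ))

    def test_recipe_from_dict(self):
        rec = recipe_from_dict({
            "name": "t",
            "base": "d" * 16 + "m" * 8 + "d" * 16,
            "edits": [{"kind": "rigid_rotate_loop", "start": 16, "end": 24, "angle": 120.0}],
        })
        assert len(rec.base) == 40
        assert rec.edits[0].params["angle"] == 120.0


class TestMakeHomologPair:
    def test_deterministic_for_same_seed(self):
        rec = PairRecipe(
            base=script_from_pbs("d" * 16 + "m" * 8 + "d" * 16),
            edits=(Edit(kind="change_dihedrals", start=16, end=24, params={}),),
        )
        a1, b1, aln1, _ = make_homolog_pair(rec, seed=21)
        a2, b2, aln2, _ = make_homolog_pair(rec, seed=21)
        assert (b1.coords("CA") == b2.coords("CA")).all()
        assert aln1.row_b == aln2.row_b
        _, b3, _, _ = make_homolog_pair(rec, seed=22)
        assert not (b1.coords("CA") == b3.coords("CA")).all()

    def test_identity_recipe_gives_identical_pair(self):
        a, b, aln, truth = make_homolog_pair(demo_recipe("identity"), seed=0)
        assert (a.coords("CA") == b.coords("CA")).all()
        assert aln.length == len(a)
        assert [r.kind for r in truth.regions] == ["SCR"]

    def test_rigid_rotation_preserves_interior_pb_letters(self, defs):
        a, b, _, _ = make_homolog_pair(demo_recipe("rigid_rotate_loop"), seed=0)
        pb_a = encode_chain(a, defs)
        pb_b = encode_chain(b, defs)
        # hinge windows (within 2 positions of the span edges) may differ;
        # the loop interior 18..22 must be untouched
        assert pb_a[18:22] == pb_b[18:22]
        disp = np.linalg.norm(a.coords("CA") - b.coords("CA"), axis=1)
        assert disp[16:24].max() > 3.0
        assert disp[:16].max() == pytest.approx(0.0) and disp[24:].max() == pytest.approx(0.0)

    def test_hinge_anchors_unmoved(self):
        a, b, _, _ = make_homolog_pair(demo_recipe("rigid_rotate_loop"), seed=0)
        assert np.allclose(a.coords("CA")[15], b.coords("CA")[15])
        assert np.allclose(a.coords("CA")[24], b.coords("CA")[24])

    @pytest.mark.parametrize("kind", ["rigid_rotate_loop", "change_dihedrals"])
    def test_segmentation_recovers_edit_span(self, kind):
        """Edited spans with > 3 A displacement come back as SVRs within
        the two-column hinge tolerance."""
        a, b, aln, truth = make_homolog_pair(demo_recipe(kind), seed=0)
        res = run_pair_objects(a, b, aln, PipelineConfig(fit_on="scr_iterative"))
        found = [r for r in res.annotated.regions if r.kind == "SVR"]
        want = [r for r in truth.regions if r.kind == "SVR"]
        assert len(found) == len(want) == 1
        assert abs(found[0].start - want[0].start) <= 2
        assert abs(found[0].end - want[0].end) <= 2

    def test_indels_produce_gapped_alignment(self):
        base = script_from_pbs("d" * 16 + "m" * 8 + "d" * 16)
        a, b, aln, truth = make_homolog_pair(
            PairRecipe(base=base, edits=(Edit(kind="insert", start=20, end=20,
                                              params={"length": 4}),)),
            seed=0,
        )
        assert aln.length == 44
        assert aln.row_a[20:24] == "----"
        assert len(b) == 44
        a, b, aln, truth = make_homolog_pair(
            PairRecipe(base=base, edits=(Edit(kind="delete", start=18, end=22),)),
            seed=0,
        )
        assert aln.row_b[18:22] == "----"
        assert len(b) == 36

    def test_substitute_aa_changes_sequence_only(self):
        base = script_from_pbs("d" * 10)
        a, b, _, _ = make_homolog_pair(
            PairRecipe(base=base, edits=(Edit(kind="substitute_aa", start=3, end=6,
                                              params={"letters": "GLY"}),)),
            seed=0,
        )
        assert b.sequence == "AAAGLYAAAA"
        assert (a.coords("CA") == b.coords("CA")).all()
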