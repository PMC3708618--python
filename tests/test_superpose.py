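"""Rigid-body superposition, fixed-frame RMSD, per-column distances, SDM."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracle_utils import rmsd_loop
from pbrealign.alignment_model import PairwiseAlignment
from pbrealign.errors import DegenerateGeometryError
from pbrealign.structure_io import transform_chain
from pbrealign.superpose import (
    RigidTransform,
    column_distances,
    fit_superposition,
    rmsd_fixed_frame,
    sdm,
)
from pbrealign.synthetic import build_backbone


@pytest.fixture
def cloud():
    return np.random.default_rng(5).normal(size=(20, 3)) * 8


class TestFitSuperposition:
    def test_identity(self, cloud):
        t, rmsd = fit_superposition(cloud, cloud)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)
        assert rmsd <= 1e-9

    def test_recovers_constructed_transform(self, cloud):
        rots = Rotation.random(20, random_state=42)
        rng = np.random.default_rng(43)
        for rot in rots:
            R = rot.as_matrix()
            t = rng.normal(size=3) * 10
            moved = cloud @ R.T + t
            # fitting the moved copy onto the original must invert (R, t)
            transform, rmsd = fit_superposition(cloud, moved)
            assert rmsd <= 1e-9
            assert np.abs(transform.rotation - R.T).max() < 1e-6
            recovered = transform.apply(moved)
            assert np.abs(recovered - cloud).max() < 1e-6

    def test_agrees_with_scipy_align_vectors(self, cloud):
        rng = np.random.default_rng(6)
        other = cloud + rng.normal(size=cloud.shape)
        transform, rmsd = fit_superposition(cloud, other)
        est, _ = Rotation.align_vectors(cloud - cloud.mean(0), other - other.mean(0))
        assert np.abs(transform.rotation - est.as_matrix()).max() < 1e-8

    def test_mirror_image_not_superposable(self):
        chiral = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirror = chiral * np.array([1, 1, -1])
        _, rmsd = fit_superposition(chiral, mirror)
        assert rmsd > 0.1

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_superposition(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            fit_superposition(line, line)

    def test_optimality_and_refit_identity(self, cloud):
        rot = Rotation.from_euler("zyx", [40, -10, 75], degrees=True).as_matrix()
        moved = cloud @ rot.T + np.array([3.0, -2.0, 9.0])
        transform, fitted = fit_superposition(cloud, moved)
        assert fitted <= rmsd_fixed_frame(cloud, moved) + 1e-12
        refit, rmsd2 = fit_superposition(cloud, transform.apply(moved))
        assert np.allclose(refit.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(refit.translation, 0.0, atol=1e-6)

    def test_reflection_rejected_in_constructor(self):
        bad = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(rotation=bad, translation=np.zeros(3))


class TestRmsdFixedFrame:
    def test_identity_and_pythagorean(self, cloud):
        assert rmsd_fixed_frame(cloud, cloud) == 0.0
        assert rmsd_fixed_frame(cloud, cloud + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_matches_per_point_loop(self, cloud):
        other = cloud + np.random.default_rng(1).normal(size=cloud.shape)
        assert rmsd_fixed_frame(cloud, other) == pytest.approx(rmsd_loop(cloud, other))

    def test_length_mismatch_rejected(self, cloud):
        with pytest.raises(ValueError):
            rmsd_fixed_frame(cloud, cloud[:-1])


class TestColumnDistances:
    def test_self_pair_identity_transform(self):
        chain = build_backbone([(-57.0, -47.0)] * 8)
        aln = PairwiseAlignment.identity(chain.sequence, chain.sequence)
        d = column_distances(aln, chain, chain, RigidTransform.identity())
        assert np.allclose(d, 0.0)

    def test_gap_columns_undefined(self):
        chain = build_backbone([(-57.0, -47.0)] * 5)
        chain4 = build_backbone([(-57.0, -47.0)] * 4)
        aln = PairwiseAlignment(row_a="AAAAA", row_b="AA-AA")
        d = column_distances(aln, chain, chain4, RigidTransform.identity())
        assert np.isnan(d[2])
        assert not np.isnan(d[0])

    def test_invariant_under_joint_rigid_motion(self):
        chain_a = build_backbone([(-57.0, -47.0)] * 10)
        chain_b = build_backbone([(-57.0, -47.0)] * 6 + [(-120.0, 130.0)] * 4)
        aln = PairwiseAlignment.identity(chain_a.sequence, chain_b.sequence)
        t1, _ = fit_superposition(chain_a.coords("CA"), chain_b.coords("CA"))
        d1 = column_distances(aln, chain_a, chain_b, t1)
        R = Rotation.from_euler("xyz", [10, 200, -35], degrees=True).as_matrix()
        shift = np.array([5.0, 1.0, -8.0])
        chain_a2 = transform_chain(chain_a, R, shift)
        chain_b2 = transform_chain(chain_b, R, shift)
        t2, _ = fit_superposition(chain_a2.coords("CA"), chain_b2.coords("CA"))
        d2 = column_distances(aln, chain_a2, chain_b2, t2)
        assert np.allclose(d1, d2, atol=1e-6)


class TestSdm:
    def test_identity_is_zero(self, cloud):
        assert sdm(cloud, cloud) == 0.0

    def test_monotone_in_rmsd_at_fixed_length(self, cloud):
        near = cloud + 0.5
        far = cloud + 5.0
        assert sdm(cloud, far) >= sdm(cloud, near)

    def test_matches_independent_transcription(self):
        """Default metric equals 100 * rmsd / n on random fragment pairs."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(3, 15))
            a = rng.normal(size=(n, 3)) * 6
            b = a + rng.normal(size=(n, 3))
            expected = 100.0 * rmsd_loop(a, b) / n
            assert sdm(a, b) == pytest.approx(expected)

    def test_empty_equivalences_rejected(self, cloud):
        with pytest.raises(ValueError):
            sdm(cloud, cloud, equivalences=[])
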