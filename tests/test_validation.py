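import numpy as np
import pytest

from oracles import horn_superpose_rmsd
from ssfold import (
    HelixSpec,
    build_chain_from_torsions,
    build_ideal_helix,
    classify_rama,
    kabsch_superpose,
    phi_psi,
    rama_summary,
    segment_rmsd,
    transform_ensemble,
)


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(0, 10, 3)


class TestPhiPsi:
    def test_ideal_helix_recovers_constructed_angles(self, backbone_helix):
        angles = phi_psi(backbone_helix, 0, "A")
        for pp in angles[1:-1]:
            assert pp.phi == pytest.approx(-57.0, abs=0.5)
            assert pp.psi == pytest.approx(-47.0, abs=0.5)

    def test_termini_are_undefined(self, backbone_helix):
        angles = phi_psi(backbone_helix, 0, "A")
        assert angles[0].phi is None and angles[0].psi is not None
        assert angles[-1].psi is None and angles[-1].phi is not None

    def test_extended_chain_trans(self):
        ens = build_chain_from_torsions([180.0] * 5, [180.0] * 5)
        for pp in phi_psi(ens, 0, "A")[1:-1]:
            assert abs(pp.phi) == pytest.approx(180.0, abs=1e-6)
            assert abs(pp.psi) == pytest.approx(180.0, abs=1e-6)

    def test_per_residue_torsions_realized(self):
        phis = [-57.0, -80.0, -120.0, 60.0, -57.0]
        psis = [-47.0, 120.0, 140.0, 40.0, -47.0]
        ens = build_chain_from_torsions(phis, psis)
        angles = phi_psi(ens, 0, "A")
        for i in range(1, 4):
            assert angles[i].phi == pytest.approx(phis[i], abs=1e-6)
            assert angles[i].psi == pytest.approx(psis[i], abs=1e-6)


class TestRamaClassification:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-57, -47, "core"),      # canonical right-handed helix
            (-119, 113, "core"),     # canonical beta strand
            (60, 60, "additional"),  # left-handed region, outside core
        ],
    )
    def test_canonical_regions(self, phi, psi, expected):
        assert classify_rama(phi, psi) == expected

    def test_far_from_any_region_disallowed(self):
        assert classify_rama(120, -60) == "disallowed"

    def test_all_helical_model_is_all_core(self, backbone_helix):
        summary = rama_summary(backbone_helix)
        assert summary.pct_core == 100.0
        assert summary.n_counted == 10  # 12 residues minus both termini

    def test_counting_excludes_gly_pro_and_termini(self):
        # 8 residues: G and P inside must not be counted
        ens = build_ideal_helix(
            HelixSpec(n_res=8, sequence="AAGPAAAA"), full_backbone=True
        )
        summary = rama_summary(ens)
        assert summary.n_counted == 4  # 8 - 2 termini - G - P

    def test_mixed_percentages(self):
        # 6 residues; 4 counted: 3 helical core + 1 left-handed additional
        phis = [-57, -57, -57, -57, 60, -57]
        psis = [-47, -47, -47, -47, 60, -47]
        ens = build_chain_from_torsions(phis, psis)
        summary = rama_summary(ens)
        assert summary.n_counted == 4
        assert summary.pct_core == 75.0
        assert summary.pct_additional == 25.0
        total = (
            summary.pct_core + summary.pct_additional
            + summary.pct_generous + summary.pct_disallowed
        )
        assert total == pytest.approx(100.0, abs=0.1)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(0, 5, (10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self):
        pts = np.random.default_rng(1).normal(0, 5, (10, 3))
        rot, trans = _random_rigid(5)
        moved = pts @ rot.T + trans
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ rot, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            a = rng.normal(0, 5, (10, 3))
            b = rng.normal(0, 5, (10, 3))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                horn_superpose_rmsd(a, b), abs=1e-9
            )

    def test_optimality_against_random_transforms(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, (12, 3))
        b = rng.normal(0, 5, (12, 3))
        best = kabsch_superpose(a, b).rmsd
        for seed in range(10):
            rot, trans = _random_rigid(seed)
            moved = b @ rot.T + trans
            trial = np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1)))
            assert best <= trial + 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSegmentRmsd:
    def test_model_vs_itself_zero(self, backbone_helix):
        res = segment_rmsd(
            backbone_helix, [(1, 6), (7, 12)], backbone_helix, [(1, 6), (7, 12)]
        )
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_atoms == 48

    def test_rigid_motion_invariance(self, backbone_helix):
        rot, trans = _random_rigid(9)
        moved = transform_ensemble(
            backbone_helix,
            type("T", (), {"rotation": rot, "translation": trans})(),
        )
        res = segment_rmsd(backbone_helix, [(1, 12)], moved, [(1, 12)])
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_raises(self, backbone_helix):
        with pytest.raises(ValueError, match="mapping"):
            segment_rmsd(backbone_helix, [(1, 6)], backbone_helix, [(1, 7)])

    def test_displaced_segment_matches_hand_bound_and_oracle(self, backbone_helix):
        # displace the second half rigidly by d = 1 Å after perfect overlap:
        # translation-only alignment splits the displacement evenly, giving
        # the hand bound RMSD ≤ |d|/2 = 0.5 Å; the exact optimum (rotation
        # free) must match the independent quaternion oracle on the same
        # atom mapping
        moved = transform_ensemble(
            backbone_helix,
            type("T", (), {"rotation": np.eye(3), "translation": np.zeros(3)})(),
        )
        d = np.array([1.0, 0.0, 0.0])
        for res in moved.residues(0, "A")[6:]:
            for atom in res.atoms.values():
                atom.pos = atom.pos + d
        res = segment_rmsd(
            backbone_helix, [(1, 6), (7, 12)], moved, [(1, 6), (7, 12)]
        )
        assert 0.0 < res.rmsd <= 0.5 + 1e-9
        pts_a = np.array(
            [a.pos for r in backbone_helix.residues(0, "A")
             for a in r.atoms.values()]
        )
        pts_b = np.array(
            [a.pos for r in moved.residues(0, "A") for a in r.atoms.values()]
        )
        assert res.rmsd == pytest.approx(
            horn_superpose_rmsd(pts_a, pts_b), abs=1e-9
        )
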