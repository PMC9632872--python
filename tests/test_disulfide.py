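import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import katz_chi3_term_min, torsion_normals
from ssfold import (
    DisulfideFixtureSpec,
    KATZ_MAX_ENERGY,
    build_disulfide_fixture,
    dihedral,
    disulfide_geometry,
    ensemble_stats,
    find_disulfides,
    katz_energy,
    strain_table,
)
from ssfold.disulfide import GeometryError
from ssfold.structure_io import StructureEnsemble


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert abs(dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))) == pytest.approx(180.0)

    def test_agrees_with_normals_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = rng.normal(0, 5, (4, 3))
            ours = dihedral(*pts)
            ref = torsion_normals(*pts)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(GeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        with pytest.raises(GeometryError):
            dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (-1, 0, 0))


class TestKatzEnergy:
    def test_all_eclipsed_maximum(self):
        assert katz_energy(0, 0, 0, 0, 0) == pytest.approx(84.50, abs=1e-9)
        assert KATZ_MAX_ENERGY == pytest.approx(84.50)

    def test_staggered_with_chi3_90(self):
        assert katz_energy(60, 60, 60, 60, 90) == pytest.approx(2.51, abs=1e-9)

    def test_grid_search_global_minimum(self):
        # χ1/χ2 terms vanish at staggered minima; the residual χ3 profile
        # bottoms out near |χ3| ≈ 83°
        expected = katz_chi3_term_min(step=0.1)
        assert expected == pytest.approx(2.04, abs=0.01)
        chi3 = np.arange(-180.0, 180.0, 0.1)
        energies = [katz_energy(60, 60, 60, 60, x) for x in (-83.0, 83.0)]
        assert min(energies) == pytest.approx(expected, abs=0.01)
        full = min(katz_energy(60, 60, 60, 60, x) for x in chi3[::10])
        assert full == pytest.approx(expected, abs=0.05)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(-180, 180), min_size=5, max_size=5))
    def test_mirror_invariance_and_bounds(self, chis):
        e = katz_energy(*chis)
        assert 0.0 <= e <= KATZ_MAX_ENERGY + 1e-9
        assert e == pytest.approx(katz_energy(*[-c for c in chis]), abs=1e-9)


class TestBridgeDetection:
    def test_bonded_pair_detected(self, ss_fixture):
        ens, _ = ss_fixture
        assert find_disulfides(ens) == [(("A", 1), ("A", 2))]

    def test_distant_sulfurs_not_detected(self, ss_fixture):
        ens, _ = ss_fixture
        # move one SG 3.5 Å away
        ens.residue(0, "A", 2).atoms["SG"].pos += np.array([5.0, 0, 0])
        assert find_disulfides(ens) == []

    def test_cysteine_without_sg_warns_and_skips(self, ss_fixture):
        ens, _ = ss_fixture
        del ens.residue(0, "A", 2).atoms["SG"]
        with pytest.warns(UserWarning, match="SG"):
            assert find_disulfides(ens) == []


class TestBridgeGeometry:
    def test_fixture_inversion_recovers_torsions(self, ss_fixture):
        ens, spec = ss_fixture
        bond = disulfide_geometry(ens, 0, (("A", 1), ("A", 2)))
        assert bond.chi1 == pytest.approx(spec.chi1, abs=1e-6)
        assert bond.chi1p == pytest.approx(spec.chi1p, abs=1e-6)
        assert bond.chi2 == pytest.approx(spec.chi2, abs=1e-6)
        assert bond.chi2p == pytest.approx(spec.chi2p, abs=1e-6)
        assert bond.chi3 == pytest.approx(spec.chi3, abs=1e-6)
        assert bond.ss_distance == pytest.approx(spec.ss_len, abs=1e-9)
        assert bond.energy == pytest.approx(
            katz_energy(spec.chi1, spec.chi1p, spec.chi2, spec.chi2p, spec.chi3),
            abs=1e-9,
        )

    def test_pair_swap_symmetry(self, ss_fixture):
        ens, _ = ss_fixture
        ab = disulfide_geometry(ens, 0, (("A", 1), ("A", 2)))
        ba = disulfide_geometry(ens, 0, (("A", 2), ("A", 1)))
        assert ba.energy == pytest.approx(ab.energy, abs=1e-9)
        assert ba.ss_distance == pytest.approx(ab.ss_distance, abs=1e-12)
        assert ba.chi1 == pytest.approx(ab.chi1p, abs=1e-9)
        assert ba.chi2 == pytest.approx(ab.chi2p, abs=1e-9)
        assert abs(ba.chi3) == pytest.approx(abs(ab.chi3), abs=1e-9)

    def test_missing_atom_named_in_error(self, ss_fixture):
        ens, _ = ss_fixture
        del ens.residue(0, "A", 1).atoms["CB"]
        with pytest.raises(GeometryError, match="CB"):
            disulfide_geometry(ens, 0, (("A", 1), ("A", 2)))


class TestEnsembleStats:
    def test_single_model_sd_zero(self, ss_fixture):
        ens, spec = ss_fixture
        stats = ensemble_stats(ens, (("A", 1), ("A", 2)))
        assert stats.n_models == 1
        assert stats.sd_energy == 0.0
        assert stats.mean_energy == pytest.approx(
            katz_energy(spec.chi1, spec.chi1p, spec.chi2, spec.chi2p, spec.chi3),
            abs=1e-9,
        )

    def test_identical_models_sd_exactly_zero(self, ss_fixture):
        ens, _ = ss_fixture
        ten = StructureEnsemble(models=[ens.models[0]] * 10, source_id="x10")
        stats = ensemble_stats(ten, (("A", 1), ("A", 2)))
        assert stats.n_models == 10
        assert stats.sd_energy == 0.0
        assert stats.sd_distance == 0.0

    def test_sample_sd_over_varying_models(self):
        specs = [
            DisulfideFixtureSpec(chi1=c, chi1p=-60, chi2=80, chi2p=80, chi3=95)
            for c in (-60.0, -55.0, -65.0)
        ]
        models = [build_disulfide_fixture(s).models[0] for s in specs]
        ens = StructureEnsemble(models=models, source_id="vary")
        stats = ensemble_stats(ens, (("A", 1), ("A", 2)))
        energies = [
            katz_energy(s.chi1, s.chi1p, s.chi2, s.chi2p, s.chi3) for s in specs
        ]
        assert stats.mean_energy == pytest.approx(np.mean(energies), abs=1e-9)
        assert stats.sd_energy == pytest.approx(np.std(energies, ddof=1), abs=1e-9)


class TestStrainTable:
    def test_empty_input_empty_table(self):
        assert strain_table([]).empty

    def test_rows_match_closed_form_energies(self):
        specs = [
            DisulfideFixtureSpec(chi1=-60, chi1p=-60, chi2=80, chi2p=80, chi3=95),
            DisulfideFixtureSpec(chi1=50, chi1p=-170, chi2=60, chi2p=-90, chi3=-100),
        ]
        inputs = [
            (build_disulfide_fixture(s), [(("A", 1), ("A", 2))]) for s in specs
        ]
        table = strain_table(inputs)
        assert len(table) == 2
        for row, spec in zip(table.itertuples(), specs):
            expected = katz_energy(spec.chi1, spec.chi1p, spec.chi2, spec.chi2p, spec.chi3)
            assert row.mean_energy == pytest.approx(expected, abs=1e-9)
            assert row.strain_energy_kJ_mol == f"{expected:.6f}"
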