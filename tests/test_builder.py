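"""Backbone construction, torsion measurement and PDB round trips."""

import math

import gemmi
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from coilgen import builder
from coilgen.builder import (
    BuildError,
    Conformation,
    DEFAULT_GEOMETRY,
    build_chain,
    dihedral,
    initial_extended,
    measure_omegas,
    measure_torsions,
    write_ensemble_pdb,
)


def gemmi_dihedral(p0, p1, p2, p3) -> float:
    return math.degrees(
        gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in (p0, p1, p2, p3)))
    )


def oracle_place(a, b, c, bond, angle, torsion):
    """Independent NeRF step using scipy rotation operators: bend the
    extended direction by (180 - angle) about the plane normal, then spin
    it about the previous bond axis by the torsion."""
    d0 = (c - b) / np.linalg.norm(c - b)
    normal = np.cross(b - a, d0)
    normal /= np.linalg.norm(normal)
    bend = Rotation.from_rotvec(np.radians(180.0 - angle) * normal)
    spin = Rotation.from_rotvec(np.radians(torsion) * d0)
    return c + bond * spin.apply(bend.apply(d0))


def oracle_backbone(sequence_len, torsions, g=DEFAULT_GEOMETRY):
    """Rotation-operator chain builder (N, CA, C only), independent of the
    package's construction; returns the CA coordinates."""
    n = np.zeros(3)
    ca = np.array([g.n_ca, 0.0, 0.0])
    ang = math.radians(g.ang_n_ca_c)
    c = ca + g.ca_c * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    cas = [ca]
    for i in range(1, sequence_len):
        n2 = oracle_place(n, ca, c, g.c_n, g.ang_ca_c_n, torsions[i - 1][1])
        ca2 = oracle_place(ca, c, n2, g.n_ca, g.ang_c_n_ca, g.omega)
        c2 = oracle_place(c, n2, ca2, g.ca_c, g.ang_n_ca_c, torsions[i][0])
        cas.append(ca2)
        n, ca, c = n2, ca2, c2
    return np.array(cas)


class TestBuildChain:
    def test_extended_poly_ala_round_trip(self):
        conf = build_chain("A" * 10, [(-65.0, 135.0)] * 10)
        measured = measure_torsions(conf)
        np.testing.assert_allclose(measured[1:, 0], -65.0, atol=1e-4)
        np.testing.assert_allclose(measured[:-1, 1], 135.0, atol=1e-4)

    def test_peptide_bond_lengths_exact(self):
        conf = build_chain("ADKLM", [(-70.0, 120.0)] * 5)
        g = DEFAULT_GEOMETRY
        for i in range(1, 5):
            d = np.linalg.norm(conf.atom(i, "C") - conf.atom(i + 1, "N"))
            assert d == pytest.approx(g.c_n, abs=1e-6)
        for i in range(1, 6):
            assert np.linalg.norm(
                conf.atom(i, "N") - conf.atom(i, "CA")
            ) == pytest.approx(g.n_ca, abs=1e-6)

    def test_helical_ca_spacing_matches_rotation_oracle(self):
        torsions = [(-58.0, -47.0)] * 5
        conf = build_chain("G" * 5, torsions)
        ca = conf.ca_coords()
        oracle_ca = oracle_backbone(5, torsions)
        np.testing.assert_allclose(ca, oracle_ca, atol=1e-8)
        turn = np.linalg.norm(ca[3] - ca[0])
        assert 4.5 < turn < 6.0  # one helical turn of CA(i)-CA(i+3)

    def test_omega_is_trans(self):
        conf = build_chain("AAAA", [(-65.0, 135.0)] * 4)
        omegas = measure_omegas(conf)
        np.testing.assert_allclose(np.abs(omegas), 180.0, atol=1e-6)

    def test_cb_chirality_constant(self):
        conf = build_chain("ACDEF", [(-80.0, 100.0)] * 5)
        impropers = [
            dihedral(conf.atom(r, "N"), conf.atom(r, "CA"),
                     conf.atom(r, "C"), conf.atom(r, "CB"))
            for r in range(1, 6)
        ]
        np.testing.assert_allclose(impropers, -122.6, atol=1e-6)

    def test_torsion_length_mismatch(self):
        with pytest.raises(BuildError):
            build_chain("AAA", [(-65.0, 135.0)] * 2)

    def test_atom_counts(self):
        conf = build_chain("AGA", [(-65.0, 135.0)] * 3)
        # 4 backbone atoms per residue + CB except Gly
        assert len(conf.atom_names) == 4 * 3 + 2
        assert conf.atom_names.count("CB") == 2


class TestInitialExtended:
    def test_interior_torsions(self):
        conf = initial_extended("AAAA")
        measured = measure_torsions(conf)
        np.testing.assert_allclose(measured[1:, 0], -65.0, atol=1e-4)
        np.testing.assert_allclose(measured[:-1, 1], 135.0, atol=1e-4)

    def test_single_glycine(self):
        conf = initial_extended("G")
        assert conf.n_res == 1
        assert len(conf.atom_names) == 4  # no CB
        measured = measure_torsions(conf)
        assert np.isnan(measured).all()

    def test_extended_longer_than_helix(self):
        ext = initial_extended("A" * 20)
        helix = build_chain("A" * 20, [(-58.0, -47.0)] * 20)
        span = lambda c: np.linalg.norm(c.ca_coords()[-1] - c.ca_coords()[0])
        assert span(ext) > span(helix)

    def test_invalid_letter_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            initial_extended("AXB")


class TestMeasureTorsions:
    def test_analytic_four_point_dihedral(self):
        # a +90 degree torsion constructed by hand: with b-c along z and
        # a along -x, d along +y gives dihedral(a,b,c,d) = +90
        a = np.array([1.0, 0.0, -1.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([0.0, 0.0, 1.0])
        d = np.array([0.0, 1.0, 2.0])
        value = dihedral(a, b, c, d)
        assert value == pytest.approx(gemmi_dihedral(a, b, c, d), abs=1e-10)
        assert abs(value) == pytest.approx(90.0, abs=1e-10)

    def test_agrees_with_gemmi_on_built_chain(self):
        conf = build_chain("AKV", [(-75.0, 145.0)] * 3)
        phi2 = gemmi_dihedral(conf.atom(1, "C"), conf.atom(2, "N"),
                              conf.atom(2, "CA"), conf.atom(2, "C"))
        measured = measure_torsions(conf)
        assert measured[1, 0] == pytest.approx(phi2, abs=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        torsions = rng.integers(-36, 36, size=(8, 2)) * 5.0
        conf = build_chain("ADKLMNPQ", torsions)
        measured = measure_torsions(conf)
        diff = np.abs((measured - torsions + 180.0) % 360.0 - 180.0)
        assert np.nanmax(diff[1:, 0]) < 1e-4
        assert np.nanmax(diff[:-1, 1]) < 1e-4

    def test_rigid_motion_invariance(self):
        conf = build_chain("AAAAA", [(-65.0, 135.0)] * 5)
        before = measure_torsions(conf)
        rot = Rotation.from_rotvec([0.4, -1.1, 2.2]).as_matrix()
        conf.coords = conf.coords @ rot.T + np.array([10.0, -3.0, 7.0])
        after = measure_torsions(conf)
        np.testing.assert_allclose(after, before, atol=1e-8)

    def test_missing_atom_reported(self):
        conf = build_chain("AAA", [(-65.0, 135.0)] * 3)
        keep = [i for i, (r, n) in enumerate(zip(conf.atom_res, conf.atom_names))
                if not (r == 2 and n == "CA")]
        conf.atom_res = conf.atom_res[keep]
        conf.atom_names = [conf.atom_names[i] for i in keep]
        conf.coords = conf.coords[keep]
        with pytest.raises(BuildError, match="CA"):
            measure_torsions(conf)


class TestPdbIO:
    def test_write_and_reparse(self, tmp_path):
        conf = build_chain("AGKM", [(-65.0, 135.0)] * 4)
        path = conf.write_pdb(tmp_path / "c.pdb")
        back = Conformation.from_pdb(path)
        assert back.sequence == "AGKM"
        assert back.atom_names == conf.atom_names
        np.testing.assert_allclose(back.coords, conf.coords, atol=1e-3)

    def test_multi_model_ensemble(self, tmp_path):
        confs = [build_chain("AAA", [(-65.0, float(psi))] * 3)
                 for psi in (135.0, 140.0, 145.0)]
        path = write_ensemble_pdb(confs, tmp_path / "ens.pdb")
        st_ = gemmi.read_structure(str(path))
        assert len(st_) == 3
        third = Conformation.from_gemmi(st_, model_index=2)
        np.testing.assert_allclose(third.coords, confs[2].coords, atol=1e-3)
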