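"""PDB parsing, Kabsch superposition/RMSD, B-factor extraction."""

import numpy as np
import pytest

from kdelsolv.structure import (
    AtomRecord,
    ParseError,
    SuperpositionResult,
    kabsch,
    read_structure,
    residue_bfactor,
    superpose_rmsd,
    write_structure,
)

from conftest import make_ca_model, random_rotation


def quaternion_superpose_rmsd(P, Q):
    """Independent oracle: optimal RMSD via the quaternion eigenvalue method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((P**2).sum() + (Q**2).sum() - 2.0 * lam) / len(P)
    return np.sqrt(max(msd, 0.0))


class TestReadWrite:
    def test_three_atom_fixture_exact_coordinates(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        assert len(model) == 3
        ca = [a for a in model.atoms if a.name == "CA"][0]
        assert ca.coords == pytest.approx((2.0, 3.0, 4.0))
        assert ca.b_factor == pytest.approx(20.0)
        assert ca.chain == "A" and ca.residue_number == 1

    def test_round_trip_through_writer(self, tiny_pdb, tmp_path):
        model = read_structure(tiny_pdb)
        out = tmp_path / "out.pdb"
        write_structure(model, out)
        back = read_structure(out)
        assert len(back) == len(model)
        for a, b in zip(model.atoms, back.atoms):
            assert b.coords == pytest.approx(a.coords, abs=1e-3)
            assert b.name == a.name and b.residue_number == a.residue_number

    def test_altloc_highest_occupancy_kept(self, altloc_pdb):
        model = read_structure(altloc_pdb)
        assert len(model) == 1
        assert model.atoms[0].coords[0] == pytest.approx(1.0)  # conformer A
        assert model.atoms[0].alt_loc == ""

    def test_empty_file_raises(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(ParseError):
            read_structure(empty)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ParseError, match="no such file"):
            read_structure(tmp_path / "absent.pdb")

    def test_negative_bfactor_rejected(self):
        with pytest.raises(ValueError, match="B-factor"):
            AtomRecord(
                serial=1, name="CA", element="C", alt_loc="",
                residue_name="ALA", chain="A", residue_number=1,
                coords=(0, 0, 0), occupancy=1.0, b_factor=-1.0,
            )


class TestSuperposition:
    def test_identical_structures_zero_rmsd(self, ca_cloud):
        m = make_ca_model(ca_cloud)
        res = superpose_rmsd(m, m)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.n_atoms_matched == len(ca_cloud)

    def test_rigid_motion_recovered(self, ca_cloud):
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        moved = ca_cloud @ R.T + np.array([4.0, -2.0, 9.0])
        res = superpose_rmsd(make_ca_model(moved), make_ca_model(ca_cloud))
        assert res.rmsd < 1e-6

    def test_symmetry_of_rmsd(self, ca_cloud):
        rng = np.random.default_rng(2)
        noisy = ca_cloud + rng.normal(scale=0.5, size=ca_cloud.shape)
        a = superpose_rmsd(make_ca_model(ca_cloud), make_ca_model(noisy))
        b = superpose_rmsd(make_ca_model(noisy), make_ca_model(ca_cloud))
        assert a.rmsd == pytest.approx(b.rmsd, abs=1e-8)

    def test_quaternion_oracle_agreement_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            P = rng.normal(scale=4.0, size=(10, 3))
            Q = rng.normal(scale=4.0, size=(10, 3))
            _, _, rmsd = kabsch(P, Q)
            assert rmsd == pytest.approx(
                quaternion_superpose_rmsd(P, Q), abs=1e-8
            )

    def test_reflection_guard_keeps_proper_rotation(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]  # mirrored cloud
        R, _, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_rmsd_monotone_under_growing_noise(self, ca_cloud):
        rng = np.random.default_rng(5)
        noise = rng.normal(size=ca_cloud.shape)
        rmsds = []
        for sigma in (0.1, 0.5, 1.0, 2.0):
            res = superpose_rmsd(
                make_ca_model(ca_cloud + sigma * noise), make_ca_model(ca_cloud)
            )
            rmsds.append(res.rmsd)
        assert np.all(np.diff(rmsds) > 0)

    def test_unmatched_residues_dropped_and_counted(self, ca_cloud):
        full = make_ca_model(ca_cloud)
        partial = make_ca_model(ca_cloud[:7])
        res = superpose_rmsd(full, partial)
        assert res.n_atoms_matched == 7
        assert len(res.unmatched_mobile) == 3

    def test_chain_mapping(self, ca_cloud):
        mob = make_ca_model(ca_cloud, chain="B")
        ref = make_ca_model(ca_cloud, chain="A")
        with pytest.raises(ValueError, match="matched"):
            superpose_rmsd(mob, ref)
        res = superpose_rmsd(mob, ref, chain_map={"B": "A"})
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_result_validates_rotation(self):
        with pytest.raises(ValueError, match="orthonormal"):
            SuperpositionResult(
                rotation=np.eye(3) * 2.0, translation=np.zeros(3),
                rmsd=0.0, n_atoms_matched=5,
            )


class TestBFactor:
    def test_mean_over_residue_atoms(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        assert residue_bfactor(model, "A", 1) == pytest.approx(20.0)

    def test_max_mode(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        assert residue_bfactor(model, "A", 1, mode="max") == pytest.approx(30.0)

    def test_single_atom_residue_identity(self, ca_cloud):
        model = make_ca_model(ca_cloud, bfactors=np.arange(10.0, 20.0))
        assert residue_bfactor(model, "A", 3) == pytest.approx(12.0)

    def test_absent_residue_raises(self, tiny_pdb):
        model = read_structure(tiny_pdb)
        with pytest.raises(KeyError, match="99"):
            residue_bfactor(model, "A", 99)
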