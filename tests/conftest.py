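"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from kdelsolv.structure import AtomRecord, StructureModel


def _pdb_line(serial, name, altloc, resname, chain, resnum, x, y, z, occ, b,
              element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_field}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three-atom PDB file with known coordinates and B-factors."""
    lines = [
        _pdb_line(1, "N", " ", "GLY", "A", 1, 1.0, 2.0, 3.0, 1.00, 10.0, "N"),
        _pdb_line(2, "CA", " ", "GLY", "A", 1, 2.0, 3.0, 4.0, 1.00, 20.0, "C"),
        _pdb_line(3, "C", " ", "GLY", "A", 1, 3.5, 4.5, 5.5, 1.00, 30.0, "C"),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One atom with alternate locations A (occ 0.6) and B (occ 0.4)."""
    lines = [
        _pdb_line(1, "CA", "A", "SER", "A", 5, 1.0, 0.0, 0.0, 0.60, 15.0, "C"),
        _pdb_line(2, "CA", "B", "SER", "A", 5, 2.0, 0.0, 0.0, 0.40, 25.0, "C"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_ca_model(coords, chain="A", bfactors=None, start_resnum=1,
                  pdb_id="SYN") -> StructureModel:
    """Synthetic Cα-only model from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if bfactors is None:
        bfactors = np.full(len(coords), 20.0)
    atoms = tuple(
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            alt_loc="",
            residue_name="ALA",
            chain=chain,
            residue_number=start_resnum + i,
            coords=tuple(xyz),
            occupancy=1.0,
            b_factor=float(b),
        )
        for i, (xyz, b) in enumerate(zip(coords, bfactors))
    )
    return StructureModel(atoms=atoms, pdb_id=pdb_id)


@pytest.fixture
def ca_cloud():
    rng = np.random.default_rng(42)
    return rng.normal(scale=5.0, size=(10, 3))


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
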