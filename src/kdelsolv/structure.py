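"""PDB structure parsing, Cα superposition/RMSD and B-factor extraction.

Crystal-structure comparisons — e.g. superposing a neutral-pH complex on
its acidic-pH counterpart and reading off the Cα RMSD, or comparing the
temperature factor of a terminal leucine against a terminal phenylalanine
— are performed on :class:`StructureModel` objects parsed from standard
PDB files (via gemmi). Superposition is least-squares Kabsch with a
reflection guard; atoms are paired by chain (after an optional mapping),
residue number and atom name, and the matched count is reported alongside
the RMSD so selection discrepancies stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "SuperpositionResult",
    "ParseError",
    "read_structure",
    "write_structure",
    "kabsch",
    "superpose_rmsd",
    "residue_bfactor",
]


class ParseError(ValueError):
    """A PDB file could not be parsed into atom records."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record (coordinates in Å, B-factor in Å²)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain: str
    residue_number: int
    coords: tuple[float, float, float]
    occupancy: float
    b_factor: float

    def __post_init__(self) -> None:
        if self.b_factor < 0:
            raise ValueError(
                f"negative B-factor on atom {self.serial} ({self.name})"
            )
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"occupancy outside [0, 1] on atom {self.serial} ({self.name})"
            )


@dataclass(frozen=True)
class StructureModel:
    """Ordered atom records plus header metadata."""

    atoms: tuple[AtomRecord, ...]
    pdb_id: str = ""
    model_number: int = 1
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        keys = [
            (a.chain, a.residue_number, a.name, a.alt_loc) for a in self.atoms
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom, altloc) records")
        object.__setattr__(self, "_index", dict(zip(keys, self.atoms)))

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, chain: str, residue_number: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        ]

    def select(
        self, names: Sequence[str] | None = None, chains: Sequence[str] | None = None
    ) -> list[AtomRecord]:
        out = []
        for a in self.atoms:
            if names is not None and a.name not in names:
                continue
            if chains is not None and a.chain not in chains:
                continue
            out.append(a)
        return out


def _pick_altloc(group: list[AtomRecord]) -> AtomRecord:
    # keep highest occupancy; tie → altloc 'A' (or lexicographically first)
    best = sorted(
        group, key=lambda a: (-a.occupancy, a.alt_loc if a.alt_loc else "A")
    )
    return best[0]


def read_structure(path, model_number: int = 1, keep_altlocs: bool = False) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Waters and other heteroatoms are retained. By default alternate
    locations are collapsed to the highest-occupancy conformer (tie →
    'A'); pass ``keep_altlocs=True`` to retain all of them.

    Raises
    ------
    ParseError
        If the file is missing, empty, or not parseable PDB (gemmi's
        diagnostic, which includes the offending line, is chained).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    try:
        model = st[model_number - 1]
    except IndexError:
        raise ParseError(
            f"{path} has {len(st)} model(s); model {model_number} requested"
        ) from None
    records: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            groups: dict[str, list[AtomRecord]] = {}
            for atom in res:
                serial += 1
                rec = AtomRecord(
                    serial=atom.serial if atom.serial else serial,
                    name=atom.name,
                    element=atom.element.name,
                    alt_loc=atom.altloc if atom.altloc != "\x00" else "",
                    residue_name=res.name,
                    chain=chain.name,
                    residue_number=res.seqid.num,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ),
                    b_factor=float(atom.b_iso),
                )
                groups.setdefault(atom.name, []).append(rec)
            for name, grp in groups.items():
                if keep_altlocs or len(grp) == 1:
                    records.extend(grp)
                else:
                    picked = _pick_altloc(grp)
                    records.append(
                        AtomRecord(
                            **{
                                **picked.__dict__,
                                "alt_loc": "",
                            }
                        )
                    )
    if not records:
        raise ParseError(f"{path} contains no atom records")
    return StructureModel(
        atoms=tuple(records), pdb_id=st.name or "", model_number=model_number
    )


def write_structure(model: StructureModel, path) -> None:
    """Write a model back to fixed-width PDB via gemmi."""
    st = gemmi.Structure()
    st.name = model.pdb_id
    md = gemmi.Model(str(model.model_number))
    chains: dict[str, gemmi.Chain] = {}
    for a in model.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.residue_number or ch[-1].name != a.residue_name:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            ch.add_residue(res)
        res = ch[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element or a.name[:1])
        atom.altloc = a.alt_loc or "\x00"
        atom.pos = gemmi.Position(*a.coords)
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        atom.serial = a.serial
        res.add_atom(atom)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of point sets (Kabsch).

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` best fits
    ``reference``. R is a proper rotation (det +1): if the best orthogonal
    transform is a reflection, the smallest singular direction is flipped.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return R, t, rmsd


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid-body superposition outcome."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_matched: int
    unmatched_mobile: tuple = ()
    unmatched_reference: tuple = ()

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        R = np.asarray(self.rotation)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")


def superpose_rmsd(
    mobile: StructureModel,
    reference: StructureModel,
    atom_names: Sequence[str] = ("CA",),
    chains: Sequence[str] | None = None,
    chain_map: Mapping[str, str] | None = None,
) -> SuperpositionResult:
    """Least-squares superposition over paired atoms; RMSD in Å.

    Atoms are paired by (mapped chain, residue number, atom name);
    ``chain_map`` maps mobile chain IDs onto reference chain IDs.
    Residues present in only one model are dropped and reported in the
    result so the matched count accompanies the RMSD.
    """
    chain_map = dict(chain_map or {})
    mob = mobile.select(names=list(atom_names), chains=chains)
    ref_atoms = {
        (a.chain, a.residue_number, a.name): a
        for a in reference.select(names=list(atom_names))
    }
    P, Q = [], []
    matched = 0
    unmatched_mob = []
    used = set()
    for a in mob:
        key = (chain_map.get(a.chain, a.chain), a.residue_number, a.name)
        r = ref_atoms.get(key)
        if r is None:
            unmatched_mob.append((a.chain, a.residue_number, a.name))
            continue
        P.append(a.coords)
        Q.append(r.coords)
        used.add(key)
        matched += 1
    unmatched_ref = tuple(sorted(set(ref_atoms) - used))
    if matched < 3:
        raise ValueError(
            f"only {matched} atoms matched (need >= 3); unmatched mobile "
            f"residues: {unmatched_mob[:10]}{'...' if len(unmatched_mob) > 10 else ''}"
        )
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_atoms_matched=matched,
        unmatched_mobile=tuple(unmatched_mob),
        unmatched_reference=unmatched_ref,
    )


def residue_bfactor(
    model: StructureModel,
    chain: str,
    residue_number: int,
    mode: str = "mean",
    side_chain_only: bool = False,
) -> float:
    """Aggregate B-factor of one residue (Å²), mean (default) or max.

    ``side_chain_only`` excludes the backbone atoms N, CA, C, O.
    """
    atoms = model.residue_atoms(chain, residue_number)
    if side_chain_only:
        atoms = [a for a in atoms if a.name not in ("N", "CA", "C", "O")]
    if not atoms:
        raise KeyError(
            f"residue {residue_number} in chain {chain!r} not found"
            + (" (or has no side-chain atoms)" if side_chain_only else "")
        )
    values = np.array([a.b_factor for a in atoms])
    if mode == "mean":
        return float(values.mean())
    if mode == "max":
        return float(values.max())
    raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
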