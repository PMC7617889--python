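"""Plain-text I/O: umbrella-window files, trajectories, role maps.

Window samples use the dialect common to WHAM tools: one two-column
whitespace file (time, cv) per window plus a metadata file listing each
window's file name, center and force constant (with temperature and unit
tags in ``#`` header lines). Trajectories round-trip as multi-model PDB
(via gemmi) or as plain XYZ whose name column carries the role tag; a
role map ("role<TAB>atom-index") accompanies PDB output so analyses can
resolve roles regardless of atom naming.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .toy_models import Frame, GCRegion, Trajectory, Window, WindowSampleSet

__all__ = [
    "write_window_set",
    "read_window_set",
    "write_trajectory_xyz",
    "read_trajectory_xyz",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_role_map",
    "read_role_map",
]


def write_window_set(ws: WindowSampleSet, directory, prefix: str = "window") -> Path:
    """Write per-window sample files and the metadata index; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = [
        f"# temperature_K {ws.temperature}",
        f"# cv_unit {ws.cv_unit}",
        f"# k_unit {ws.k_unit}",
    ]
    for i, w in enumerate(ws.windows):
        fname = f"{prefix}_{i:03d}.dat"
        t = np.arange(len(w.samples), dtype=float)
        np.savetxt(directory / fname, np.column_stack([t, w.samples]), fmt="%.10g")
        meta_lines.append(f"{fname} {w.center:.10g} {w.force_constant:.10g}")
    meta = directory / f"{prefix}_meta.dat"
    meta.write_text("\n".join(meta_lines) + "\n")
    return meta


def read_window_set(meta_path) -> WindowSampleSet:
    """Read a window set from its metadata file (see :func:`write_window_set`)."""
    meta_path = Path(meta_path)
    temperature, cv_unit, k_unit = 298.15, "nm", "kcal/mol"
    windows = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if parts[0] == "temperature_K":
                temperature = float(parts[1])
            elif parts[0] == "cv_unit":
                cv_unit = parts[1]
            elif parts[0] == "k_unit":
                k_unit = " ".join(parts[1:])
            continue
        fname, center, k = line.split()
        data = np.loadtxt(meta_path.parent / fname, ndmin=2)
        windows.append(
            Window(center=float(center), force_constant=float(k), samples=data[:, 1])
        )
    if not windows:
        raise ValueError(f"no windows listed in {meta_path}")
    return WindowSampleSet(
        windows=tuple(windows),
        temperature=temperature,
        cv_unit=cv_unit,
        k_unit=k_unit,
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    """Plain XYZ with the role tag in the name column."""
    lines = []
    for i, frame in enumerate(traj.frames):
        lines.append(str(len(frame.atom_labels)))
        lines.append(f"frame {i} t={i * traj.timestep:g}")
        for (name, role), xyz in zip(frame.atom_labels, frame.coords):
            lines.append(f"{role} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_xyz(path, timestep: float = 1.0) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        body = lines[i + 2 : i + 2 + n]
        labels, coords = [], []
        for row in body:
            parts = row.split()
            role = parts[0]
            labels.append((role.split(":")[-1], role))
            coords.append([float(v) for v in parts[1:4]])
        frames.append(Frame(atom_labels=tuple(labels), coords=np.array(coords)))
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(frames=tuple(frames), timestep=timestep)


def _role_to_pdb_fields(role: str, index: int) -> tuple[str, str, int]:
    # crude but reversible mapping: residue tag before ':' names the
    # residue, the remainder names the atom; unique resnum per role group
    if ":" in role:
        res, atom = role.split(":", 1)
    else:
        res, atom = "MOL", role
    return res[:3].upper() or "MOL", atom[:4] or f"X{index}", index + 1


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Multi-model PDB (MODEL/ENDMDL per frame); pair with a role map."""
    st = gemmi.Structure()
    st.name = "trajectory"
    for m, frame in enumerate(traj.frames):
        model = gemmi.Model(str(m + 1))
        chain = gemmi.Chain("A")
        for i, ((name, role), xyz) in enumerate(zip(frame.atom_labels, frame.coords)):
            resname, atomname, resnum = _role_to_pdb_fields(role, i)
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = atomname
            element = "H" if atomname.upper().startswith("H") else (name[:1] or "C")
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def read_trajectory_pdb(path, role_map: dict[int, str] | None = None,
                        timestep: float = 1.0) -> Trajectory:
    """Read a multi-model PDB; roles from ``role_map`` (atom index → role)
    or reconstructed as "RESNAME:ATOMNAME" when none is given."""
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path} contains no models")
    frames = []
    for model in st:
        labels, coords = [], []
        i = 0
        for chain in model:
            for res in chain:
                for atom in res:
                    role = (
                        role_map[i]
                        if role_map is not None
                        else f"{res.name}:{atom.name}"
                    )
                    labels.append((atom.name, role))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    i += 1
        frames.append(Frame(atom_labels=tuple(labels), coords=np.array(coords)))
    return Trajectory(frames=tuple(frames), timestep=timestep)


def write_role_map(traj: Trajectory, path) -> None:
    lines = [f"{role}\t{i}" for i, (_, role) in enumerate(traj.atom_labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_role_map(path) -> dict[int, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        role, idx = line.rsplit("\t", 1) if "\t" in line else line.rsplit(":", 1)
        out[int(idx)] = role.strip()
    return out
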