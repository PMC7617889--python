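"""Collective variables for peptide unbinding and proton transfer.

Two coordinates drive the umbrella-sampling analyses:

* the *pocket distance* — Euclidean distance from the mass-weighted center
  of the Cα atoms of five pocket residues (9, 44, 64, 124, 162) to the
  peptide's N-terminal nitrogen; the unbinding coordinate, in nm.
* the *center of excess charge* (CEC) — a signed sum of pairwise-distance
  differences tracking a proton leaving the His12 Nδ, hopping across the
  bridging water, and arriving on the Asp9 carboxylate:

      CEC = D(H12:N, H12:H) − D(W:O, H12:H)
          + D(W:O, W:H1)    − D(D9:O, W:H1)
          + D(W:O, W:H2)    − D(D9:O, W:H2)

  Each difference pair grows as its hydrogen moves from the donor-side
  reference toward the acceptor-side one, so the coordinate decreases
  from the His-protonated end toward the Asp-protonated end on the
  conventional 0.1 → −0.4 nm axis. Which numeric endpoint corresponds to
  which protonation state is recorded as metadata on the schedule, not
  assumed by the math.

Both CVs are invariant under rigid rotation and translation of the frame.
Harmonic bias energies and the apo/bound window schedules used for the
proton-transfer profiles are provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .toy_models import Frame, Trajectory
from .units import ANGSTROM_PER_NM, KCAL_PER_KJ

__all__ = [
    "PocketCVSpec",
    "CECSpec",
    "BiasSpec",
    "CECWindowSchedule",
    "pocket_distance_cv",
    "cec_value",
    "bias_energy",
    "cec_window_schedule",
    "assign_water_hydrogens",
    "evaluate_cv_series",
]

logger = logging.getLogger(__name__)

_POCKET_RESIDUES = (9, 44, 64, 124, 162)


@dataclass(frozen=True)
class PocketCVSpec:
    """Roles defining the unbinding distance CV.

    ``pocket_atom_roles`` must resolve to exactly five Cα atoms;
    ``masses`` weight the pocket center (equal masses when omitted —
    flagged in the log, since Cα atoms are all carbon this is exact for
    the default selection).
    """

    pocket_atom_roles: tuple[str, ...] = tuple(
        f"R{i}:CA" for i in _POCKET_RESIDUES
    )
    terminus_role: str = "PEP:N"
    masses: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.pocket_atom_roles) != 5:
            raise ValueError(
                f"pocket CV requires exactly 5 pocket atoms, got "
                f"{len(self.pocket_atom_roles)}"
            )
        if self.masses is not None and len(self.masses) != 5:
            raise ValueError("masses must match the 5 pocket atoms")


def pocket_distance_cv(frame: Frame, spec: PocketCVSpec | None = None) -> float:
    """Pocket-center → peptide-N distance, in nm."""
    if spec is None:
        spec = PocketCVSpec()
    pocket = np.array([frame.position(r) for r in spec.pocket_atom_roles])
    if spec.masses is None:
        logger.debug("pocket CV using equal-mass center for %d atoms", len(pocket))
        com = pocket.mean(axis=0)
    else:
        m = np.asarray(spec.masses, dtype=float)
        com = (pocket * m[:, None]).sum(axis=0) / m.sum()
    term = frame.position(spec.terminus_role)
    return float(np.linalg.norm(term - com)) / ANGSTROM_PER_NM


@dataclass(frozen=True)
class CECSpec:
    """Atom roles entering the CEC coordinate (six distinct atoms).

    The histidine nitrogen is the Nδ — the solvent-facing nitrogen, the
    only plausible exit route for the proton at low pH. The bridging
    water's two hydrogens keep a fixed H1/H2 assignment for the whole
    trajectory (see :func:`assign_water_hydrogens`).
    """

    his_n: str = "H12:N"
    his_h: str = "H12:H"
    water_o: str = "W:O"
    water_h1: str = "W:H1"
    water_h2: str = "W:H2"
    asp_o: str = "D9:O"

    def __post_init__(self) -> None:
        roles = (
            self.his_n, self.his_h, self.water_o,
            self.water_h1, self.water_h2, self.asp_o,
        )
        if len(set(roles)) != 6:
            raise ValueError("CEC requires six distinct atom roles")

    @property
    def roles(self) -> tuple[str, ...]:
        return (
            self.his_n, self.his_h, self.water_o,
            self.water_h1, self.water_h2, self.asp_o,
        )


def cec_value(frame: Frame, spec: CECSpec | None = None) -> float:
    """Evaluate the CEC proton-transfer coordinate on one frame, in nm."""
    if spec is None:
        spec = CECSpec()
    hn = frame.position(spec.his_n)
    hh = frame.position(spec.his_h)
    wo = frame.position(spec.water_o)
    wh1 = frame.position(spec.water_h1)
    wh2 = frame.position(spec.water_h2)
    do = frame.position(spec.asp_o)

    def d(a, b):
        return float(np.linalg.norm(a - b))

    cec = (
        d(hn, hh) - d(wo, hh)
        + d(wo, wh1) - d(do, wh1)
        + d(wo, wh2) - d(do, wh2)
    )
    return cec / ANGSTROM_PER_NM


def assign_water_hydrogens(
    traj: Trajectory,
    water_h_roles: tuple[str, str] = ("W:Ha", "W:Hb"),
    asp_o_role: str = "D9:O",
    **spec_kwargs,
) -> CECSpec:
    """Fix the W:H1/W:H2 assignment for a trajectory.

    The hydrogen closer to the Asp9 oxygen in the first frame becomes H1
    (ties → lower atom index); the assignment then stays fixed so the CEC
    series cannot jump from frame-to-frame relabeling.
    """
    first = traj.frames[0]
    do = first.position(asp_o_role)
    d = [float(np.linalg.norm(first.position(r) - do)) for r in water_h_roles]
    idx = [first.index_of(r) for r in water_h_roles]
    if d[0] < d[1] or (d[0] == d[1] and idx[0] <= idx[1]):
        h1, h2 = water_h_roles
    else:
        h2, h1 = water_h_roles
    return CECSpec(water_h1=h1, water_h2=h2, asp_o=asp_o_role, **spec_kwargs)


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias ½·k·(cv − center)².

    ``force_constant`` is interpreted in ``k_unit`` per cv-unit²; the
    proton-transfer protocol's default is 20000 kJ/mol/nm².
    """

    center: float
    force_constant: float = 20000.0
    k_unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")

    @property
    def k_kcal(self) -> float:
        if self.k_unit.lower().startswith("kj"):
            return self.force_constant * KCAL_PER_KJ
        if self.k_unit.lower().startswith("kcal"):
            return self.force_constant
        raise ValueError(f"unrecognised force-constant unit {self.k_unit!r}")


def bias_energy(cv: float, bias: BiasSpec) -> float:
    """Harmonic bias energy at ``cv``, in kcal/mol."""
    if not np.isfinite(cv):
        raise ValueError("cv must be finite")
    return 0.5 * bias.k_kcal * (cv - bias.center) ** 2


@dataclass(frozen=True)
class CECWindowSchedule:
    """Umbrella schedule along the CEC axis with endpoint metadata."""

    state: str
    centers: tuple[float, ...]
    bias: tuple[BiasSpec, ...]
    endpoint_note: str = (
        "endpoint assignment (His- vs Asp-protonated) is metadata; the "
        "positive end of the axis lies nearer the His-protonated well"
    )

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    @property
    def spacing(self) -> float:
        return float(abs(np.diff(self.centers)).mean())


def cec_window_schedule(
    state: str, force_constant: float = 20000.0, k_unit: str = "kJ/mol"
) -> CECWindowSchedule:
    """Proton-transfer window schedules along the CEC (nm).

    apo: 17 windows from 0 to −0.4, step 0.025 nm; bound: 21 windows from
    0.1 to −0.4, step 0.025 nm.
    """
    if state == "apo":
        start = 0.0
    elif state == "bound":
        start = 0.1
    else:
        raise ValueError(f"state must be 'apo' or 'bound', got {state!r}")
    n = int(round((start - (-0.4)) / 0.025)) + 1
    centers = tuple(np.round(start - 0.025 * np.arange(n), 6))
    bias = tuple(
        BiasSpec(center=c, force_constant=force_constant, k_unit=k_unit)
        for c in centers
    )
    return CECWindowSchedule(state=state, centers=centers, bias=bias)


def evaluate_cv_series(traj: Trajectory, cv_fn, *args, **kwargs) -> np.ndarray:
    """Per-frame (time, cv) series for any frame-wise CV function."""
    t = np.arange(traj.n_frames) * traj.timestep
    v = np.array([cv_fn(f, *args, **kwargs) for f in traj.frames])
    return np.column_stack([t, v])
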