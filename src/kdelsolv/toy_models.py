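"""Synthetic-data generators with analytic ground truth.

Every downstream analysis in this package (grand-canonical titration,
umbrella-sampling/WHAM, hydrogen-bond network statistics, RMSF) is exercised
on systems built here, for which the exact answer is known in closed form or
by construction:

* :func:`make_gc_toy_system` — a pocket with 1–3 discrete water sites whose
  grand-canonical occupancy as a function of the Adams value ``B`` is an
  exact logistic (or, with site–site coupling, a three-site enumeration).
* :func:`sample_umbrella_windows` — exact draws from the biased Boltzmann
  density of a stated 1D potential, via inverse-CDF sampling on a fine grid.
* :func:`make_network_trajectory` — multi-frame coordinates in which the
  His12–W1–W2–peptide hydrogen-bond chain is intact in a prescribed fraction
  of frames and each atom fluctuates with a prescribed RMSF amplitude.

These toys stand in for the membrane-protein molecular dynamics that the
statistics were designed for; they reproduce the *shape* of the data (site
occupancies, biased samples, bonded/broken frames), not water energetics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .units import beta as _beta

__all__ = [
    "ProtonationState",
    "GCRegion",
    "ToyPocketSystem",
    "Frame",
    "Trajectory",
    "Window",
    "WindowSampleSet",
    "HID",
    "HIE",
    "HIP",
    "DEFAULT_REGION_DIMS",
    "NETWORK_ROLES",
    "make_gc_toy_system",
    "sample_umbrella_windows",
    "make_network_trajectory",
]

#: GCMC region dimensions (Å): the box enclosing the two bridging waters.
DEFAULT_REGION_DIMS: tuple[float, float, float] = (3.23, 3.38, 5.78)

_VALID_LABELS = ("HID", "HIE", "HIP")


@dataclass(frozen=True)
class ProtonationState:
    """Histidine tautomer/protonation state of the pocket.

    HID carries the proton on Nδ, HIE on Nε (both net neutral); HIP is
    doubly protonated with net charge +1. ``site_energies`` give the
    state-dependent well depth offered to each water site (kcal/mol,
    negative = favourable).
    """

    label: str
    site_energies: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValueError(
                f"protonation label must be one of {_VALID_LABELS}, got {self.label!r}"
            )
        for v in self.site_energies.values():
            if not np.isfinite(v):
                raise ValueError("site energies must be finite")

    @property
    def charge(self) -> int:
        """Net formal charge: +1 for HIP, 0 for HID/HIE."""
        return 1 if self.label == "HIP" else 0


HID = ProtonationState("HID")
HIE = ProtonationState("HIE")
HIP = ProtonationState("HIP")


@dataclass(frozen=True)
class GCRegion:
    """Orthorhombic grand-canonical sampling region (Å)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dims: tuple[float, float, float] = DEFAULT_REGION_DIMS

    def __post_init__(self) -> None:
        if not all(d > 0 for d in self.dims):
            raise ValueError(f"region dims must be positive, got {self.dims}")

    @property
    def volume(self) -> float:
        dx, dy, dz = self.dims
        return dx * dy * dz

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean membership test for points of shape (..., 3)."""
        xyz = np.asarray(xyz, dtype=float)
        rel = np.abs(xyz - np.asarray(self.center))
        half = np.asarray(self.dims) / 2.0
        return np.all(rel <= half, axis=-1)


@dataclass(frozen=True)
class ToyPocketSystem:
    """Discrete-site pocket with analytic grand-canonical occupancy.

    Each of ``n_sites`` sites binds at most one water with energy
    ``site_energies[i]`` (kcal/mol). Optional pairwise ``coupling`` adds
    J_ij when sites i and j are simultaneously occupied, emulating the
    W1–W2 hydrogen bond. When a ligand is present, at most two sites are
    accessible — the peptide's excluded volume caps pocket capacity.
    """

    n_sites: int
    site_energies: tuple[float, ...]
    region: GCRegion
    protonation: ProtonationState
    ligand_present: bool
    temperature: float
    coupling: tuple[tuple[int, int, float], ...] = ()

    @property
    def accessible_sites(self) -> tuple[int, ...]:
        if self.ligand_present:
            return tuple(range(min(self.n_sites, 2)))
        return tuple(range(self.n_sites))

    # -- analytic truth ---------------------------------------------------

    def _coupling_energy(self, occ: Sequence[int]) -> float:
        e = 0.0
        for i, j, jij in self.coupling:
            if i < len(occ) and j < len(occ) and occ[i] and occ[j]:
                e += jij
        return e

    def occupancy_truth(self, adams_B: float) -> np.ndarray:
        """Exact per-site mean occupancy ⟨n_i⟩ at Adams value ``B``.

        Independent sites follow the two-state grand-canonical closed form
        ⟨n_i⟩ = e^(B−βU_i) / (1 + e^(B−βU_i)); with coupling the 2^k
        occupancy states (k ≤ 3) are enumerated exactly. Inaccessible
        sites report zero.
        """
        b = _beta(self.temperature)
        acc = self.accessible_sites
        out = np.zeros(self.n_sites)
        if not self.coupling:
            for i in acc:
                x = adams_B - b * self.site_energies[i]
                out[i] = _logistic(x)
            return out
        # exact enumeration over accessible-site occupancy states
        weights = {}
        for occ in itertools.product((0, 1), repeat=len(acc)):
            e = sum(o * self.site_energies[s] for o, s in zip(occ, acc))
            full = [0] * self.n_sites
            for o, s in zip(occ, acc):
                full[s] = o
            e += self._coupling_energy(full)
            weights[occ] = np.exp(adams_B * sum(occ) - b * e)
        z = sum(weights.values())
        for k, s in enumerate(acc):
            out[s] = sum(w for occ, w in weights.items() if occ[k]) / z
        return out

    def mean_occupancy_truth(self, adams_B: float) -> float:
        """Exact total mean occupancy ⟨N⟩(B)."""
        return float(self.occupancy_truth(adams_B).sum())


def _logistic(x: float) -> float:
    # numerically safe e^x/(1+e^x)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


def make_gc_toy_system(
    n_sites: int,
    site_energies: Sequence[float],
    protonation: ProtonationState = HIP,
    ligand_present: bool = False,
    region_dims: Sequence[float] = DEFAULT_REGION_DIMS,
    temperature: float = 298.15,
    coupling: Sequence[tuple[int, int, float]] = (),
) -> ToyPocketSystem:
    """Build a discrete-site grand-canonical toy pocket.

    Parameters
    ----------
    n_sites : int
        Number of water sites, 1–3 (the crystallographic pocket hosts at
        most three waters in the apo state, two when the peptide is bound).
    site_energies : sequence of float
        Well depth per site, kcal/mol (negative = favourable).
    protonation : ProtonationState
        Histidine state label carried as metadata; state-dependent
        energetics are expressed through ``site_energies``.
    ligand_present : bool
        When True, only the first two sites are accessible.
    region_dims : (dx, dy, dz) in Å
        Grand-canonical region; defaults to the box enclosing W1/W2.
    coupling : sequence of (i, j, J_ij)
        Optional pairwise occupancy coupling in kcal/mol.
    """
    if not (1 <= int(n_sites) <= 3):
        raise ValueError(f"n_sites must be in 1..3, got {n_sites}")
    energies = tuple(float(e) for e in site_energies)
    if len(energies) != n_sites:
        raise ValueError(
            f"expected {n_sites} site energies, got {len(energies)}"
        )
    if not all(np.isfinite(e) for e in energies):
        raise ValueError("site energies must be finite")
    for i, j, _ in coupling:
        if not (0 <= i < n_sites and 0 <= j < n_sites and i != j):
            raise ValueError(f"invalid coupling pair ({i}, {j})")
    return ToyPocketSystem(
        n_sites=int(n_sites),
        site_energies=energies,
        region=GCRegion(dims=tuple(float(d) for d in region_dims)),
        protonation=protonation,
        ligand_present=bool(ligand_present),
        temperature=float(temperature),
        coupling=tuple((int(i), int(j), float(v)) for i, j, v in coupling),
    )


# ---------------------------------------------------------------------------
# umbrella-window sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """One umbrella window: harmonic bias ½k(x−center)² plus its samples."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")
        if len(self.samples) < 1:
            raise ValueError("window must carry at least one sample")


@dataclass(frozen=True)
class WindowSampleSet:
    """Umbrella windows with declared units.

    ``cv_unit`` tags the collective-variable axis ("nm" or "A");
    ``k_unit`` tags the force-constant energy scale ("kcal/mol" or
    "kJ/mol" per cv_unit²).
    """

    windows: tuple[Window, ...]
    temperature: float
    cv_unit: str = "nm"
    k_unit: str = "kcal/mol"


def sample_umbrella_windows(
    true_potential: Callable[[np.ndarray], np.ndarray],
    windows: Sequence[tuple[float, float]],
    n_samples: int,
    temperature: float = 298.15,
    seed: int | None = None,
    cv_unit: str = "nm",
    grid_points: int = 20001,
) -> WindowSampleSet:
    """Draw exact samples from each biased density ∝ exp(−β[U(x)+½k(x−c)²]).

    Sampling is inverse-CDF on a fine grid: the support of each window is
    expanded until the biased density is negligible at both edges, the CDF
    is accumulated by trapezoid, and uniform variates are mapped through
    its inverse. Identical seeds give identical output.

    Raises
    ------
    ValueError
        If the biased density is non-finite or not integrable on the grid
        (diagnostic includes the offending window).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")
    rng = np.random.default_rng(seed)
    b = _beta(temperature)
    out = []
    for c, k in windows:
        if k <= 0:
            raise ValueError(f"force constant must be > 0, got {k}")
        sigma = np.sqrt(1.0 / (b * k))
        half_width = 8.0 * sigma
        for _ in range(12):
            grid = np.linspace(c - half_width, c + half_width, grid_points)
            energy = np.asarray(true_potential(grid), dtype=float) + 0.5 * k * (grid - c) ** 2
            if not np.all(np.isfinite(energy)):
                raise ValueError(
                    f"biased energy non-finite for window (center={c}, k={k})"
                )
            logw = -b * energy
            logw -= logw.max()
            w = np.exp(logw)
            edge = max(w[0], w[-1])
            if edge < 1e-12:
                break
            half_width *= 2.0
        else:
            raise ValueError(
                f"biased density for window (center={c}, k={k}) does not decay "
                "on the grid; potential may be non-integrable under this bias"
            )
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) * 0.5 * np.diff(grid))])
        if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
            raise ValueError(
                f"density mass vanished for window (center={c}, k={k})"
            )
        cdf /= cdf[-1]
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        out.append(Window(center=float(c), force_constant=float(k), samples=samples))
    return WindowSampleSet(
        windows=tuple(out), temperature=float(temperature), cv_unit=cv_unit
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Frame:
    """Labeled particle coordinates (Å) for one time point.

    ``atom_labels`` is an ordered list of (name, role) pairs; roles are
    the stable identifiers the analysis layers look atoms up by, e.g.
    ``"W1:O"`` for the first bridging water's oxygen.
    """

    atom_labels: tuple[tuple[str, str], ...]
    coords: np.ndarray
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.atom_labels), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.atom_labels)} atom labels"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(role for _, role in self.atom_labels)

    def index_of(self, role: str) -> int:
        for i, (_, r) in enumerate(self.atom_labels):
            if r == role:
                return i
        raise RoleLookupError(role)

    def position(self, role: str) -> np.ndarray:
        return self.coords[self.index_of(role)]


class RoleLookupError(KeyError):
    """An atom role required by an analysis is absent from the frame."""

    def __init__(self, role: str):
        super().__init__(role)
        self.role = role

    def __str__(self) -> str:  # KeyError quotes its arg; be explicit
        return f"no atom with role {self.role!r} in frame"


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames with constant atom labeling.

    ``region`` optionally records the pocket region (used by the
    water-network occupancy statistic); ``timestep`` is in arbitrary
    units and only used for output time columns.
    """

    frames: tuple[Frame, ...]
    timestep: float = 1.0
    region: GCRegion | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory requires at least one frame")
        labels = self.frames[0].atom_labels
        for f in self.frames[1:]:
            if f.atom_labels != labels:
                raise ValueError("atom labeling must be constant across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def atom_labels(self) -> tuple[tuple[str, str], ...]:
        return self.frames[0].atom_labels

    def coords_array(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])

    def role_series(self, role: str) -> np.ndarray:
        i = self.frames[0].index_of(role)
        return self.coords_array()[:, i, :]


#: Roles emitted by :func:`make_network_trajectory`, in atom order.
NETWORK_ROLES: tuple[tuple[str, str], ...] = (
    ("ND1", "H12:N"),
    ("HD1", "H12:H"),
    ("O", "W1:O"),
    ("H1", "W1:H1"),
    ("H2", "W1:H2"),
    ("O", "W2:O"),
    ("OD1", "D9:O"),
    ("C", "PEP:C-term"),
)

# Reference geometry (Å) with the full His12→W1→W2→peptide chain intact:
# donor–acceptor separations of 2.8–2.9 Å, donor–H–acceptor collinear.
_NETWORK_GEOMETRY: dict[str, tuple[float, float, float]] = {
    "H12:N": (0.0, 0.0, 0.0),
    "H12:H": (1.0, 0.0, 0.0),
    "W1:O": (2.9, 0.0, 0.0),
    "W1:H1": (3.87, 0.0, 0.0),
    "W1:H2": (2.60, 0.93, 0.0),
    "W2:O": (5.8, 0.0, 0.0),
    "D9:O": (2.9, 3.0, 0.0),
    "PEP:C-term": (8.6, 0.0, 0.0),
}

#: Displacement applied to W2:O in broken frames — far beyond any H-bond
#: cutoff and outside the pocket region.
_BREAK_SHIFT = np.array([0.0, 0.0, 6.0])


def make_network_trajectory(
    n_frames: int,
    network_fraction: float,
    fluctuation_amplitudes: Mapping[str, float] | float | None = None,
    seed: int | None = None,
    timestep: float = 1.0,
) -> Trajectory:
    """Trajectory with a prescribed water-network occupancy and per-atom RMSF.

    Exactly ``round(network_fraction * n_frames)`` frames have the full
    His12→W1→W2→C-terminus hydrogen-bond chain intact with both waters in
    the pocket region; in the remaining frames one water (W2) is displaced
    beyond the hydrogen-bond cutoff and out of the region. Broken frames
    are placed by a seeded permutation, so the output is reproducible.

    ``fluctuation_amplitudes`` sets the target RMSF (Å) per role (scalar =
    same for all atoms); displacements are isotropic Gaussians with
    per-axis σ = a/√3 so the expected RMSF equals ``a``. The default (no
    noise) makes the planted occupancy exact frame counting.
    """
    if not (0.0 <= network_fraction <= 1.0):
        raise ValueError(
            f"network_fraction must be in [0, 1], got {network_fraction}"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    roles = [r for _, r in NETWORK_ROLES]
    base = np.array([_NETWORK_GEOMETRY[r] for r in roles])

    if fluctuation_amplitudes is None:
        amps = np.zeros(len(roles))
    elif isinstance(fluctuation_amplitudes, Mapping):
        amps = np.array([float(fluctuation_amplitudes.get(r, 0.0)) for r in roles])
    else:
        amps = np.full(len(roles), float(fluctuation_amplitudes))
    if np.any(amps < 0):
        raise ValueError("fluctuation amplitudes must be non-negative")

    n_bonded = int(round(network_fraction * n_frames))
    order = rng.permutation(n_frames)
    broken = np.zeros(n_frames, dtype=bool)
    broken[order[n_bonded:]] = True

    noise = rng.normal(0.0, 1.0, size=(n_frames, len(roles), 3))
    noise *= (amps / np.sqrt(3.0))[None, :, None]

    w2 = roles.index("W2:O")
    frames = []
    for t in range(n_frames):
        coords = base + noise[t]
        if broken[t]:
            coords[w2] = coords[w2] + _BREAK_SHIFT
        frames.append(Frame(atom_labels=NETWORK_ROLES, coords=coords))

    w1o = np.array(_NETWORK_GEOMETRY["W1:O"])
    w2o = np.array(_NETWORK_GEOMETRY["W2:O"])
    region = GCRegion(center=tuple((w1o + w2o) / 2.0), dims=(6.0, 6.0, 6.0))
    return Trajectory(frames=tuple(frames), timestep=timestep, region=region)
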