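"""Hydrogen-bond network occupancy and per-atom fluctuation statistics.

The pocket's water network is the ordered hydrogen-bond chain
His12 → W1 → W2 → peptide C-terminus. Its *occupancy* — the fraction of
frames in which every link holds and both waters sit inside the pocket
region — is the stability statistic distinguishing the protonated
(network held ~100% of the time) from the deprotonated (~60%) receptor.
Per-pair occupancies and per-atom RMSF complete the picture.

Hydrogen bonds are detected geometrically: donor–acceptor distance ≤
3.5 Å and donor–H–acceptor deviation from linearity ≤ 30° (community
defaults; a distance-only mode supports hydrogen-free fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structure import kabsch
from .toy_models import Frame, GCRegion, Trajectory

__all__ = [
    "HBondCriterion",
    "NetworkSpec",
    "OccupancyReport",
    "DEFAULT_NETWORK",
    "hbond_present",
    "pair_occupancy",
    "network_occupancy",
    "rmsf",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond test.

    ``max_angle_deviation`` is measured from linear donor–H–acceptor
    (0° = perfectly linear). With ``require_hydrogen`` False the angle
    test is skipped and only the donor–acceptor distance applies.
    """

    max_da_distance: float = 3.5
    max_angle_deviation: float = 30.0
    require_hydrogen: bool = True

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.max_angle_deviation <= 180.0):
            raise ValueError("angle deviation must be in (0, 180]")


def hbond_present(
    frame: Frame,
    donor: str,
    acceptor: str,
    hydrogen: str | None = None,
    criterion: HBondCriterion | None = None,
) -> bool:
    """Is a hydrogen bond donor→acceptor present in this frame?"""
    if criterion is None:
        criterion = HBondCriterion()
    d = frame.position(donor)
    a = frame.position(acceptor)
    if np.linalg.norm(a - d) > criterion.max_da_distance:
        return False
    if not criterion.require_hydrogen:
        return True
    if hydrogen is None:
        raise ValueError(
            "criterion requires a hydrogen role; pass one or use "
            "require_hydrogen=False for distance-only detection"
        )
    h = frame.position(hydrogen)
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return True  # coincident atoms: degenerate but legal geometry
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    deviation = 180.0 - np.degrees(np.arccos(cosang))
    return bool(deviation <= criterion.max_angle_deviation)


def pair_occupancy(
    traj: Trajectory,
    donor: str,
    acceptor: str,
    hydrogen: str | None = None,
    criterion: HBondCriterion | None = None,
) -> float:
    """Fraction of frames in which the donor→acceptor H-bond is present."""
    if traj.n_frames < 1:
        raise ValueError("trajectory is empty")
    hits = sum(
        hbond_present(f, donor, acceptor, hydrogen, criterion)
        for f in traj.frames
    )
    return hits / traj.n_frames


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered H-bond chain as (donor, hydrogen-or-None, acceptor) triples.

    Pairs without a hydrogen role are tested distance-only. ``water_roles``
    are the oxygens that must lie inside the pocket region for the network
    to count as formed.
    """

    pairs: tuple[tuple[str, str | None, str], ...]
    water_roles: tuple[str, ...] = ("W1:O", "W2:O")

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("network chain must contain at least one pair")
        seen = [(d, a) for d, _, a in self.pairs]
        if len(set(seen)) != len(seen):
            raise ValueError("network chain pairs must be distinct")


#: The crystallographic pocket chain: His12 → W1 → W2 → peptide C-terminus.
DEFAULT_NETWORK = NetworkSpec(
    pairs=(
        ("H12:N", "H12:H", "W1:O"),
        ("W1:O", "W1:H1", "W2:O"),
        ("W2:O", None, "PEP:C-term"),
    )
)


@dataclass(frozen=True)
class OccupancyReport:
    """Per-pair and whole-network occupancy fractions over a trajectory."""

    per_pair: Mapping[tuple[str, str], float]
    network_fraction: float
    n_frames: int

    def __post_init__(self) -> None:
        for f in self.per_pair.values():
            if not (0.0 <= f <= 1.0):
                raise ValueError("occupancy fractions must lie in [0, 1]")
        if self.per_pair and self.network_fraction > min(self.per_pair.values()) + 1e-12:
            raise ValueError(
                "network fraction cannot exceed any per-pair occupancy"
            )


def network_occupancy(
    traj: Trajectory,
    network: NetworkSpec = DEFAULT_NETWORK,
    criterion: HBondCriterion | None = None,
    region: GCRegion | None = None,
) -> OccupancyReport:
    """Occupancy of the full H-bond chain, waters required in the pocket.

    A frame counts toward the network fraction only if every chain bond
    holds *and* every water oxygen lies inside ``region`` (defaulting to
    the trajectory's recorded pocket region; when neither is available
    the region test is vacuous).
    """
    if criterion is None:
        criterion = HBondCriterion()
    if region is None:
        region = traj.region
    dist_only = HBondCriterion(
        max_da_distance=criterion.max_da_distance,
        max_angle_deviation=criterion.max_angle_deviation,
        require_hydrogen=False,
    )
    pair_hits = {(d, a): 0 for d, _, a in network.pairs}
    net_hits = 0
    for f in traj.frames:
        all_ok = True
        for d, h, a in network.pairs:
            crit = criterion if h is not None else dist_only
            ok = hbond_present(f, d, a, h, crit)
            pair_hits[(d, a)] += ok
            all_ok &= ok
        if all_ok and region is not None:
            for w in network.water_roles:
                if not region.contains(f.position(w)):
                    all_ok = False
                    break
        net_hits += all_ok
    n = traj.n_frames
    return OccupancyReport(
        per_pair={k: v / n for k, v in pair_hits.items()},
        network_fraction=net_hits / n,
        n_frames=n,
    )


def rmsf(
    traj: Trajectory,
    selection: Sequence[str] | None = None,
    superpose: bool = False,
) -> dict[str, float]:
    """Per-atom root-mean-square fluctuation about the time-mean position (Å).

    With ``superpose`` each frame is first least-squares fitted onto the
    first frame over the selected atoms, removing rigid-body motion.
    Requires at least two frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    roles = list(selection) if selection is not None else list(
        r for _, r in traj.atom_labels
    )
    idx = [traj.frames[0].index_of(r) for r in roles]
    coords = traj.coords_array()[:, idx, :]
    if superpose:
        ref = coords[0]
        fitted = np.empty_like(coords)
        for t in range(coords.shape[0]):
            R, tvec, _ = kabsch(coords[t], ref)
            fitted[t] = coords[t] @ R.T + tvec
        coords = fitted
    mean = coords.mean(axis=0)
    msd = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)
    return dict(zip(roles, np.sqrt(msd)))
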