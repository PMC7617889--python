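"""Water transfer free energies from titration curves, and the apo/bound cycle.

Grand-canonical integration (GCI): the Adams value B at which a site is
half-occupied locates its binding strength on the B axis; integrating the
occupancy curve,

    ∫ ⟨N⟩ dB  ≈  n_w · (B_max − B̄½),

gives the mean half-occupancy point B̄½ per water. Against a bulk-water
reference Adams value B_bulk (the B at which the region would exchange
water with bulk at equal stability), the per-water transfer free energy is

    ΔG_solv = k_B·T · (B̄½ − B_bulk).

Sign convention: ΔG_solv is the free energy of bringing a water from bulk
into the pocket, so *negative means the water is more stable in the pocket
than in bulk*. The apo/bound solvation cycle then reads

    ΔΔG = ΔG_solv(bound) − ΔG_solv(apo),

with negative ΔΔG indicating the water network is stabilized by the bound
peptide — the quantity tabulated per ligand and histidine protonation
state. Because the free energy is per transferred water, it is unchanged
by sites that never titrate (e.g. the third pocket site blocked by the
ligand), which is the point of defining solvation against bulk rather
than vacuum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gcmc import TitrationResult, adams_from_mu
from .toy_models import GCRegion
from .units import WATER_EXCESS_MU_KCAL, kbt as _kbt

__all__ = [
    "TransferFreeEnergy",
    "SolvationCycle",
    "TransitionNotBracketedError",
    "default_bulk_reference_B",
    "gci_transfer_free_energy",
    "solvation_cycle",
    "cycle_table",
]

TRANSFER_DEFINITION = "pocket→bulk per water"


class TransitionNotBracketedError(ValueError):
    """The titration grid does not span the occupancy transition."""


@dataclass(frozen=True)
class TransferFreeEnergy:
    """Per-water transfer free energy between pocket and bulk (kcal/mol).

    ``value`` follows the bulk→pocket sign convention (negative = more
    stable in the pocket). ``definition`` is a fixed tag so cycles are
    only ever composed from like quantities.
    """

    value: float
    sd: float
    temperature: float
    definition: str = TRANSFER_DEFINITION
    n_waters: int = 1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SolvationCycle:
    """Apo/bound water solvation cycle: ΔΔG = ΔG_solv(bound) − ΔG_solv(apo)."""

    dG_solv_bound: float
    dG_solv_apo: float
    ddG: float
    sd_bound: float
    sd_apo: float
    sd_ddG: float
    interpretation: str
    temperature: float


def default_bulk_reference_B(
    region: GCRegion | None = None, temperature: float = 298.15
) -> float:
    """Bulk-equivalence Adams value for ``region``.

    B_bulk = βμ′_water + ln(ρ_bulk·V): the Adams value at which the region
    holds water at bulk stability, using the excess hydration free energy
    of water (−6.2 kcal/mol) and the region volume.
    """
    if region is None:
        region = GCRegion()
    return adams_from_mu(WATER_EXCESS_MU_KCAL, region.volume, temperature)


def _integrate_curve(grid_asc, n_asc, n_waters, bulk_reference_B, kT):
    integral = np.trapezoid(n_asc, grid_asc)
    b_half = grid_asc[-1] - integral / n_waters
    return kT * (b_half - bulk_reference_B)


def gci_transfer_free_energy(
    titration: TitrationResult,
    bulk_reference_B: float | None = None,
    temperature: float | None = None,
    region: GCRegion | None = None,
    per_water: bool = True,
) -> TransferFreeEnergy:
    """Grand-canonical integration of a titration curve.

    The occupancy curve is integrated by trapezoid on its own grid between
    the empty and occupied plateaus; the repeat-level curves are integrated
    individually and their standard deviation is reported as the error.

    Parameters
    ----------
    bulk_reference_B : float, optional
        Bulk-equivalence Adams value; defaults to
        :func:`default_bulk_reference_B` for ``region`` (or the standard
        pocket region).
    per_water : bool
        Report the free energy per transferred water (default). With
        False, the total for all titrating waters is returned — relevant
        when two waters titrate as one network.

    Raises
    ------
    TransitionNotBracketedError
        If mean occupancy varies by ≤ 0.5 across the grid, or the curve
        has not plateaued at the high-B end; extend the grid.
    """
    if temperature is None:
        temperature = titration.temperature
    kT = _kbt(temperature)
    if bulk_reference_B is None:
        bulk_reference_B = default_bulk_reference_B(region, temperature)

    grid = np.asarray(titration.adams_grid, dtype=float)
    mean = np.asarray(titration.mean_N, dtype=float)
    order = np.argsort(grid)
    grid_asc, mean_asc = grid[order], mean[order]

    span = mean_asc.max() - mean_asc.min()
    if span <= 0.5:
        raise TransitionNotBracketedError(
            f"occupancy varies by only {span:.3f} across the grid "
            f"[{grid_asc[0]}, {grid_asc[-1]}]; extend the Adams grid to "
            "bracket the transition"
        )
    n_waters = int(round(mean_asc.max()))
    if n_waters < 1 or mean_asc[-1] < 0.8 * n_waters:
        raise TransitionNotBracketedError(
            "occupancy has not plateaued at the high-B end of the grid; "
            "extend the grid upward"
        )

    per_repeat = np.array(
        [
            _integrate_curve(
                grid_asc, np.asarray(rep)[order], n_waters, bulk_reference_B, kT
            )
            for rep in titration.repeat_N
        ]
    )
    value = _integrate_curve(grid_asc, mean_asc, n_waters, bulk_reference_B, kT)
    sd = float(per_repeat.std(ddof=1)) if len(per_repeat) > 1 else 0.0
    if not per_water:
        value *= n_waters
        sd *= n_waters
    return TransferFreeEnergy(
        value=float(value), sd=sd, temperature=float(temperature),
        n_waters=n_waters,
    )


def solvation_cycle(
    dG_bound: TransferFreeEnergy, dG_apo: TransferFreeEnergy
) -> SolvationCycle:
    """Compose the apo/bound solvation cycle: ΔΔG = bound − apo.

    Errors are propagated as independent: sd(ΔΔG) = √(sd_b² + sd_a²).
    A negative ΔΔG means the water is more stable in the bound state.
    """
    if dG_bound.definition != dG_apo.definition:
        raise ValueError(
            f"definition mismatch: {dG_bound.definition!r} vs {dG_apo.definition!r}"
        )
    if abs(dG_bound.temperature - dG_apo.temperature) > 1e-9:
        raise ValueError(
            f"temperature mismatch: {dG_bound.temperature} K vs "
            f"{dG_apo.temperature} K"
        )
    ddg = dG_bound.value - dG_apo.value
    sd = float(np.hypot(dG_bound.sd, dG_apo.sd))
    if ddg < 0:
        note = "water more stable in the bound state"
    elif ddg > 0:
        note = "water more stable in the apo state"
    else:
        note = "neutral"
    return SolvationCycle(
        dG_solv_bound=dG_bound.value,
        dG_solv_apo=dG_apo.value,
        ddG=ddg,
        sd_bound=dG_bound.sd,
        sd_apo=dG_apo.sd,
        sd_ddG=sd,
        interpretation=note,
        temperature=dG_bound.temperature,
    )


def cycle_table(
    cycles: Mapping[str, Mapping[str, SolvationCycle]],
    states: tuple[str, ...] = ("HID", "HIE", "HIP"),
) -> str:
    """Render ΔΔG ± sd as a TSV table: rows = peptide ligand, columns = states."""
    lines = ["Peptide ligand\t" + "\t".join(states)]
    for ligand, by_state in cycles.items():
        cells = []
        for s in states:
            c = by_state.get(s)
            cells.append("" if c is None else f"{c.ddG:.1f} ± {c.sd_ddG:.1f}")
        lines.append(ligand + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
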