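"""Physical constants and unit conversions used across the package.

Internal conventions: lengths in Å unless a series is explicitly tagged
``nm`` (umbrella-sampling collective variables follow the nm convention of
the pulling literature); energies in kcal/mol.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K: float = 1.987204259e-3

#: kcal per kJ (thermochemical calorie).
KCAL_PER_KJ: float = 1.0 / 4.184

#: Å per nm.
ANGSTROM_PER_NM: float = 10.0

#: Bulk water number density at ambient conditions, Å^-3.
WATER_NUMBER_DENSITY_A3: float = 0.0334

#: Excess (hydration) chemical potential of bulk water, kcal/mol.
WATER_EXCESS_MU_KCAL: float = -6.2


def kbt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B·T) in mol/kcal."""
    return 1.0 / kbt(temperature)


def kj_to_kcal(x: float) -> float:
    return x * KCAL_PER_KJ


def nm_to_angstrom(x: float) -> float:
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x: float) -> float:
    return x / ANGSTROM_PER_NM
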