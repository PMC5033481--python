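"""Physical constants and the exact unit conversions shared by the pipeline.

The pipeline works internally in kcal·mol⁻¹, Å, amu and elementary charges.
Spectroscopic force constants are traditionally quoted in mdyne/Å, so the
single derived factor ``MDYNE_PER_A_TO_KCAL`` (≈143.93) is the bridge between
the spectroscopy literature and the force-field files.  It is derived once
from N_A and the thermochemical calorie and must never be re-hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "Constants",
    "CONSTANTS",
    "MDYNE_PER_A_TO_KCAL",
    "atomic_mass",
    "convert_force_constant",
    "diatomic_frequency",
    "wavenumber_from_eigenvalue",
    "FORCE_CONSTANT_UNITS",
]

# Standard atomic weights (amu), conventional (not isotopic) values.
_ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904,
}

_SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]
ATOMIC_NUMBERS: Mapping[str, int] = MappingProxyType(
    {s: i + 1 for i, s in enumerate(_SYMBOLS)}
)
ELEMENT_OF_Z: Mapping[int, str] = MappingProxyType(
    {i + 1: s for i, s in enumerate(_SYMBOLS)}
)


@dataclass(frozen=True)
class Constants:
    """Immutable CODATA-based physical constants (thermochemical calorie)."""

    avogadro: float = 6.02214076e23          # mol^-1
    cal_to_joule: float = 4.184              # J/cal, thermochemical
    speed_of_light: float = 2.99792458e10    # cm/s
    amu_to_kg: float = 1.66053906660e-27     # kg/amu
    bohr_to_angstrom: float = 0.529177210903  # A/bohr
    hartree_to_kcal: float = 627.5094740631   # kcal/mol per hartree
    atomic_masses: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(dict(_ATOMIC_MASSES))
    )


CONSTANTS = Constants()

# 1 mdyne/A = 1e-8 N per 1e-10 m = 1e-18 J/A^2; per mole and in kcal:
MDYNE_PER_A_TO_KCAL: float = 1e-18 * CONSTANTS.avogadro / (
    1000.0 * CONSTANTS.cal_to_joule
)
# 1 mdyne/A = 1e-8 N / 1e-10 m = 100 N/m.
MDYNE_PER_A_TO_N_PER_M: float = 100.0

FORCE_CONSTANT_UNITS = ("mdyne_per_A", "kcal_per_mol_A2", "N_per_m")

# factor converting *to* mdyne/A from each tag
_TO_MDYNE = {
    "mdyne_per_A": 1.0,
    "kcal_per_mol_A2": 1.0 / MDYNE_PER_A_TO_KCAL,
    "N_per_m": 1.0 / MDYNE_PER_A_TO_N_PER_M,
}


def atomic_mass(element: str) -> float:
    """Standard atomic weight in amu for an element symbol."""
    try:
        return CONSTANTS.atomic_masses[element]
    except KeyError:
        raise KeyError(f"unknown element symbol: {element!r}") from None


def convert_force_constant(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a force constant between mdyne/Å, kcal·mol⁻¹·Å⁻² and N/m.

    The map is linear and exact; converting a value to its own unit is the
    identity.  Unknown unit tags are rejected by name.
    """
    for tag in (from_unit, to_unit):
        if tag not in _TO_MDYNE:
            raise ValueError(
                f"unknown force-constant unit tag {tag!r}; "
                f"expected one of {FORCE_CONSTANT_UNITS}"
            )
    if from_unit == to_unit:
        return value
    return value * _TO_MDYNE[from_unit] / _TO_MDYNE[to_unit]


def diatomic_frequency(k_mdyne_per_A: float, m1_amu: float, m2_amu: float) -> float:
    """Harmonic wavenumber (cm⁻¹) of a diatomic with spring constant ``k``.

    Closed form (1/2πc)·sqrt(k/μ) with μ = m1·m2/(m1+m2); the analytic
    cross-check for the matrix normal-mode engine.
    """
    if m1_amu <= 0 or m2_amu <= 0:
        raise ValueError("atomic masses must be positive")
    if k_mdyne_per_A < 0:
        raise ValueError("force constant must be non-negative")
    mu_kg = (m1_amu * m2_amu / (m1_amu + m2_amu)) * CONSTANTS.amu_to_kg
    k_si = k_mdyne_per_A * MDYNE_PER_A_TO_N_PER_M  # N/m
    omega = math.sqrt(k_si / mu_kg)  # rad/s
    return omega / (2.0 * math.pi * CONSTANTS.speed_of_light)


# sqrt(kcal/mol/A^2/amu) -> cm^-1 : nu = _WAVENUMBER_SCALE * sqrt(lambda)
_WAVENUMBER_SCALE: float = math.sqrt(
    1000.0 * CONSTANTS.cal_to_joule
    / (CONSTANTS.avogadro * CONSTANTS.amu_to_kg * 1e-20)
) / (2.0 * math.pi * CONSTANTS.speed_of_light)


def wavenumber_from_eigenvalue(lam: float) -> float:
    """Signed wavenumber (cm⁻¹) from a mass-weighted Hessian eigenvalue.

    ``lam`` is in kcal·mol⁻¹·Å⁻²·amu⁻¹; negative eigenvalues (imaginary
    modes) map to negative wavenumbers by convention.
    """
    return math.copysign(_WAVENUMBER_SCALE * math.sqrt(abs(lam)), lam)


def eigenvalue_from_wavenumber(nu: float) -> float:
    """Inverse of :func:`wavenumber_from_eigenvalue`."""
    return math.copysign((nu / _WAVENUMBER_SCALE) ** 2, nu)
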