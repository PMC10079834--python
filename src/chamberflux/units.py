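"""Physical constants and unit conversions shared across the package.

Internal conventions:

* molar fluxes in nmol m-2 s-1
* mass fluxes in mg gas m-2 d-1
* mole fractions in ppm (1e-6 mol mol-1) for every gas; an N2O trace
  recorded in ppb is converted on ingest and its unit label retained
* cavity temperature in K, pressure in kPa
"""

from __future__ import annotations

R_GAS = 8.314462618
"""Ideal-gas constant, J mol-1 K-1."""

MOLAR_MASS = {
    "n2o": 44.013,
    "ch4": 16.043,
    "co2": 44.009,
}
"""Molar mass of each gas, g mol-1."""

GASES = tuple(MOLAR_MASS)

SECONDS_PER_DAY = 86400.0

#: Multiplier taking a mole fraction in the named unit to ppm.
_UNIT_TO_PPM = {"ppm": 1.0, "ppb": 1e-3}


def mole_fraction_to_ppm(value, unit: str):
    """Convert a mole fraction (scalar or array) in ``unit`` to ppm."""
    try:
        return value * _UNIT_TO_PPM[unit]
    except KeyError:
        raise ValueError(f"unknown mole-fraction unit {unit!r}") from None


def molar_density(temp_k: float, press_kpa: float) -> float:
    """Molar density of an ideal gas, mol m-3, at T (K) and P (kPa)."""
    if temp_k <= 0 or press_kpa <= 0:
        raise ValueError("temperature and pressure must be positive")
    return press_kpa * 1000.0 / (R_GAS * temp_k)


def molar_to_mass_flux(flux_nmol_m2_s: float, gas: str) -> float:
    """nmol gas m-2 s-1 -> mg gas m-2 d-1."""
    return flux_nmol_m2_s * MOLAR_MASS[gas] * SECONDS_PER_DAY * 1e-6


def mass_to_molar_flux(flux_mg_m2_d: float, gas: str) -> float:
    """mg gas m-2 d-1 -> nmol gas m-2 s-1."""
    return flux_mg_m2_d / (MOLAR_MASS[gas] * SECONDS_PER_DAY * 1e-6)
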