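"""Unit conversions for stable-isotope enrichments and tracer doses.

Internally every enrichment is expressed as *tracer mole fraction per mol
of body water*: mol of heavy atoms (2H or 18O) per mol of water.  For
oxygen this equals the 18O atom fraction (one O per water); for hydrogen
it is twice the 2H atom fraction (two H per water).  With that convention
the dilution space is simply

    N (mol water) = excess tracer in dose (mol) / excess mole fraction

for both isotopes, which keeps the pool-size arithmetic identical across
isotopes and directly testable.

Two input dialects are accepted: delta per-mil relative to VSMOW, and ppm
atom-fraction excess.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .constants import (
    MASS_2H,
    MASS_1H,
    MASS_18O,
    MASS_16O,
    MASS_H2O,
    VSMOW_RATIO_2H,
    VSMOW_RATIO_18O,
)


class Isotope(str, Enum):
    H2 = "H2"
    O18 = "O18"


#: heavy-atom sites per water molecule
ATOM_SITES = {Isotope.H2: 2, Isotope.O18: 1}

_STD_RATIO = {Isotope.H2: VSMOW_RATIO_2H, Isotope.O18: VSMOW_RATIO_18O}


def delta_to_atom_fraction(delta_permil, isotope: Isotope):
    """Convert delta per-mil (vs VSMOW) to heavy-isotope atom fraction."""
    r_std = _STD_RATIO[Isotope(isotope)]
    ratio = r_std * (1.0 + np.asarray(delta_permil, dtype=float) / 1000.0)
    return ratio / (1.0 + ratio)


def atom_fraction_to_delta(atom_fraction, isotope: Isotope):
    """Inverse of :func:`delta_to_atom_fraction`."""
    x = np.asarray(atom_fraction, dtype=float)
    ratio = x / (1.0 - x)
    return (ratio / _STD_RATIO[Isotope(isotope)] - 1.0) * 1000.0


def to_water_mole_fraction(values, units: str, isotope: Isotope):
    """Normalize raw enrichment values to tracer mol per mol water.

    Parameters
    ----------
    values : array-like
        Raw enrichments as recorded.
    units : {"delta_permil", "ppm_excess"}
        ``delta_permil`` is interpreted against VSMOW; ``ppm_excess`` is
        atom-fraction excess above the standard, in parts per million.
    isotope : Isotope
        Which tracer, deciding the per-water site multiplicity.
    """
    iso = Isotope(isotope)
    sites = ATOM_SITES[iso]
    if units == "delta_permil":
        return sites * delta_to_atom_fraction(values, iso)
    if units == "ppm_excess":
        std = _STD_RATIO[iso] / (1.0 + _STD_RATIO[iso])
        return sites * (np.asarray(values, dtype=float) * 1e-6 + std)
    raise ValueError(f"unknown enrichment units {units!r}")


def water_mole_fraction_to_delta(mole_fraction, isotope: Isotope):
    """Convert tracer-per-water mole fraction back to delta per-mil."""
    iso = Isotope(isotope)
    return atom_fraction_to_delta(
        np.asarray(mole_fraction, dtype=float) / ATOM_SITES[iso], iso
    )


def dose_excess_mol(dose_g: float, atom_percent: float, isotope: Isotope) -> float:
    """Moles of heavy atoms in a dose, in excess of natural abundance.

    The dose is a mass of labeled water with the stated heavy-atom
    percentage (e.g. 99.8 atom% 2H2O or 10.0 atom% H2-18O).  The molar
    mass is interpolated between the light and fully labeled species.
    """
    if dose_g <= 0:
        raise ValueError("dose mass must be positive")
    if not 0 < atom_percent <= 100:
        raise ValueError("atom percent must lie in (0, 100]")
    iso = Isotope(isotope)
    x = atom_percent / 100.0
    nat = _STD_RATIO[iso] / (1.0 + _STD_RATIO[iso])
    if iso is Isotope.H2:
        molar_mass = MASS_H2O + 2 * (MASS_2H - MASS_1H) * x
        sites = 2
    else:
        molar_mass = MASS_H2O + (MASS_18O - MASS_16O) * x
        sites = 1
    mol_water = dose_g / molar_mass
    return mol_water * sites * (x - nat)
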