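"""DPPC monolayer coverage: surface concentration, mean molecular area,
and phase classification.

The deposited mass per interfacial area Gamma (mg/m^2) fixes the mean area
per lipid molecule,

    area = M / (Gamma * N_A),

because DPPC is insoluble in the aqueous subphase.  The area in turn places
the monolayer on its 2D phase diagram: a gas-like state above 90 A^2 per
molecule, liquid-expanded / LE-LC coexistence between, and a predominantly
liquid-condensed (LC) film at 48-58 A^2.  Areas below 48 A^2 are outside
the tabulated ranges and flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro

#: Molar mass of DPPC (C40H80NO8P), g/mol.  Named constant so other lipids
#: can be analyzed by overriding it.
DPPC_MOLAR_MASS = 734.04

PHASE_GAS = "gas"
PHASE_LE = "LE_or_coexistence"
PHASE_LC = "LC"
PHASE_BEYOND_LC = "beyond_LC"

#: Phase boundaries in A^2/molecule; boundary membership goes to the denser
#: (smaller-area) side, and the LE/coexistence band is a single label since
#: the LE <-> coexistence boundary is not resolved here.
GAS_BOUNDARY_A2 = 90.0
LC_UPPER_A2 = 58.0
LC_LOWER_A2 = 48.0


def area_per_molecule(gamma_mg_m2: float,
                      molar_mass: float = DPPC_MOLAR_MASS) -> float:
    """Mean molecular area (A^2/molecule) at surface concentration
    ``gamma_mg_m2`` (mg/m^2).  Exact arithmetic: M / (Gamma N_A), converted
    from m^2 to A^2 (x 1e20)."""
    if gamma_mg_m2 <= 0:
        raise ValueError("surface concentration must be > 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    gamma_g_m2 = gamma_mg_m2 * 1e-3
    return molar_mass / (gamma_g_m2 * Avogadro) * 1e20


def concentration_for_area(area_A2: float,
                           molar_mass: float = DPPC_MOLAR_MASS) -> float:
    """Inverse of :func:`area_per_molecule`: the Gamma (mg/m^2) at which the
    mean molecular area equals ``area_A2``."""
    if area_A2 <= 0:
        raise ValueError("area must be > 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    return molar_mass / (area_A2 * 1e-20 * Avogadro) * 1e3


def classify_phase(area_A2: float) -> str:
    """Phase label for a mean molecular area (A^2/molecule):
    > 90 gas; (58, 90] LE or LE-LC coexistence; [48, 58] LC; < 48 beyond the
    tabulated LC range (flagged)."""
    if area_A2 <= 0:
        raise ValueError("area must be > 0")
    if area_A2 > GAS_BOUNDARY_A2:
        return PHASE_GAS
    if area_A2 > LC_UPPER_A2:
        return PHASE_LE
    if area_A2 >= LC_LOWER_A2:
        return PHASE_LC
    return PHASE_BEYOND_LC


@dataclass(frozen=True)
class MonolayerState:
    """A monolayer condition: concentration, molecular area and phase."""
    gamma_mg_m2: float
    area_A2: float
    phase: str
    molar_mass: float = DPPC_MOLAR_MASS

    @classmethod
    def from_concentration(cls, gamma_mg_m2: float,
                           molar_mass: float = DPPC_MOLAR_MASS
                           ) -> "MonolayerState":
        area = area_per_molecule(gamma_mg_m2, molar_mass)
        return cls(gamma_mg_m2=gamma_mg_m2, area_A2=area,
                   phase=classify_phase(area), molar_mass=molar_mass)
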