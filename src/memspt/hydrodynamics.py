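"""Membrane-inclusion hydrodynamics: Saffman–Delbrück and the
Petrov–Schwille closed form of the HPW model.

A disk of radius ``a`` embedded in a flat membrane of interfacial (surface)
viscosity ``eta`` [Pa s m], sandwiched between bulk fluids of viscosities
``mu1`` (superphase) and ``mu2`` (subphase) [Pa s], diffuses with a
coefficient controlled by the reduced radius

    epsilon = a (mu1 + mu2) / eta

— the ratio of bulk to membrane drag length scales.  For epsilon << 1 the
Saffman–Delbrück logarithmic law holds,

    D_SD = k_B T / (4 pi eta) * (ln(2/epsilon) - gamma_E),

while the Hughes–Pailthorpe–White (HPW) theory covers all epsilon but only
implicitly.  Petrov & Schwille give an explicit rational-function
approximation to HPW, accurate over many decades of epsilon:

    D(eps) = k_B T / (4 pi eta)
             * [ln(2/eps) - gamma_E + 4 eps/pi - (eps^2/2) ln(2/eps)]
             / [1 - (eps^3/pi) ln(2/eps) + c1 eps^b1 / (1 + c2 eps^b2)].

The fitted constants c1, b1, c2, b2 below are the published values of that
approximation.  All formulas are SI internally; helpers convert to the
um^2/s used elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BOLTZMANN = 1.380649e-23          # J/K (exact, SI)
EULER_GAMMA = float(np.euler_gamma)

#: Bulk viscosities for the default experimental condition: air superphase
#: and water subphase at 21 degC.
AIR_VISCOSITY = 1.8e-5            # Pa s
WATER_VISCOSITY_21C = 9.8e-4      # Pa s

#: Validity envelope of the explicit approximation (reduced radius).
EPSILON_ENVELOPE = (1e-6, 1e6)


@dataclass(frozen=True)
class PSConstants:
    """Fitted constants of the Petrov–Schwille explicit HPW approximation
    (published values; pinned by the test suite)."""
    c1: float = 0.73761
    b1: float = 2.74819
    c2: float = 0.52119
    b2: float = 0.51465


DEFAULT_PS_CONSTANTS = PSConstants()


@dataclass(frozen=True)
class MembraneSystem:
    """A membrane inclusion and its hydrodynamic environment (SI units).

    Parameters
    ----------
    radius : float
        Inclusion (particle) radius ``a``, metres.
    interfacial_viscosity : float
        Membrane surface viscosity ``eta``, Pa s m.
    superphase_viscosity, subphase_viscosity : float
        Bulk viscosities ``mu1``, ``mu2``, Pa s.  Defaults: air above,
        water at 21 degC below.
    temperature : float
        Absolute temperature, K.
    """

    radius: float
    interfacial_viscosity: float
    superphase_viscosity: float = AIR_VISCOSITY
    subphase_viscosity: float = WATER_VISCOSITY_21C
    temperature: float = 294.0

    def __post_init__(self) -> None:
        for name in ("radius", "interfacial_viscosity", "superphase_viscosity",
                     "subphase_viscosity", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def epsilon(system: MembraneSystem) -> float:
    """Reduced radius epsilon = a (mu1 + mu2) / eta (dimensionless)."""
    return (system.radius
            * (system.superphase_viscosity + system.subphase_viscosity)
            / system.interfacial_viscosity)


def petrov_schwille_D(system: MembraneSystem,
                      constants: PSConstants = DEFAULT_PS_CONSTANTS) -> float:
    """Diffusivity of a membrane-embedded disk from the explicit
    Petrov–Schwille approximation to HPW, in m^2/s.

    Valid for reduced radius within ``EPSILON_ENVELOPE``; outside it a
    ``ValueError`` names the envelope.
    """
    eps = epsilon(system)
    lo, hi = EPSILON_ENVELOPE
    if not (lo <= eps <= hi):
        raise ValueError(
            f"reduced radius epsilon={eps:.3g} outside the validity envelope "
            f"[{lo:g}, {hi:g}] of the explicit approximation")
    c = constants
    L = np.log(2.0 / eps)
    numerator = L - EULER_GAMMA + 4.0 * eps / np.pi - 0.5 * eps ** 2 * L
    denominator = (1.0 - (eps ** 3 / np.pi) * L
                   + c.c1 * eps ** c.b1 / (1.0 + c.c2 * eps ** c.b2))
    D = (BOLTZMANN * system.temperature
         / (4.0 * np.pi * system.interfacial_viscosity)) * numerator / denominator
    return float(D)


def saffman_delbruck_D(system: MembraneSystem) -> float:
    """Saffman–Delbrück small-epsilon diffusivity, m^2/s.

    Requires epsilon < 2 exp(-gamma_E) so the logarithmic factor
    ln(2/epsilon) - gamma_E is positive.
    """
    eps = epsilon(system)
    eps_max = 2.0 * np.exp(-EULER_GAMMA)
    if eps >= eps_max:
        raise ValueError(
            f"epsilon={eps:.3g} >= 2 exp(-gamma)={eps_max:.3g}: outside the "
            "Saffman-Delbruck regime")
    return float(BOLTZMANN * system.temperature
                 / (4.0 * np.pi * system.interfacial_viscosity)
                 * (np.log(2.0 / eps) - EULER_GAMMA))


def predict_curve(radius: float, viscosity_table: pd.DataFrame,
                  superphase_viscosity: float = AIR_VISCOSITY,
                  subphase_viscosity: float = WATER_VISCOSITY_21C,
                  temperature: float = 294.0,
                  constants: PSConstants = DEFAULT_PS_CONSTANTS) -> pd.DataFrame:
    """Predicted D versus surface concentration from an interfacial-viscosity
    table.

    ``viscosity_table`` needs columns ``gamma_mg_m2`` and ``eta_Pa_s_m``
    (surface concentration and the interfacial viscosity measured at it).
    Returns one row per input row, sorted by gamma, with columns
    ``gamma_mg_m2, eta_Pa_s_m, epsilon, D_um2_s``.  Rows whose reduced
    radius falls outside the validity envelope get ``NaN`` and a warning;
    the remainder are computed.
    """
    required = {"gamma_mg_m2", "eta_Pa_s_m"}
    if len(viscosity_table) == 0:
        raise ValueError("viscosity table is empty")
    if not required.issubset(viscosity_table.columns):
        raise ValueError(f"viscosity table needs columns {sorted(required)}")
    rows = []
    for _, row in viscosity_table.iterrows():
        eta = float(row["eta_Pa_s_m"])
        system = MembraneSystem(radius=radius, interfacial_viscosity=eta,
                                superphase_viscosity=superphase_viscosity,
                                subphase_viscosity=subphase_viscosity,
                                temperature=temperature)
        eps = epsilon(system)
        try:
            D = petrov_schwille_D(system, constants) * 1e12  # m^2/s -> um^2/s
        except ValueError as exc:
            warnings.warn(f"gamma={row['gamma_mg_m2']}: {exc}", stacklevel=2)
            D = np.nan
        rows.append((float(row["gamma_mg_m2"]), eta, eps, D))
    out = pd.DataFrame(rows, columns=["gamma_mg_m2", "eta_Pa_s_m",
                                      "epsilon", "D_um2_s"])
    return out.sort_values("gamma_mg_m2", kind="stable").reset_index(drop=True)
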