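"""Internal unit system and physical constants.

Internal units throughout the package:

========  =============
quantity  unit
========  =============
length    nm
time      ps
energy    kJ/mol
mass      g/mol
charge    e
T         K
pressure  kJ/mol/nm^3 (converted to Pa / GPa only at I/O boundaries)
========  =============

With these units ``1 (g/mol) * (nm/ps)^2 = 1 kJ/mol`` exactly, so kinetic
energy, potential energy and forces need no conversion factors inside the
integrator.
"""

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_K = 138.935458

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: molar mass of water (SPC/E), g/mol
M_WATER = 18.0154

#: 1 Pa expressed in internal pressure units (kJ mol^-1 nm^-3)
PA_TO_INTERNAL = 1.0e-27 * N_AVOGADRO / 1000.0  # J/m^3 -> kJ/mol/nm^3

#: 1 internal pressure unit in Pa
INTERNAL_TO_PA = 1.0 / PA_TO_INTERNAL

#: 1 internal pressure unit in GPa
INTERNAL_TO_GPA = INTERNAL_TO_PA * 1.0e-9

#: kcal/mol per kJ/mol
KJ_TO_KCAL = 1.0 / 4.184

#: saturation vapor pressure of SPC/E water at 300 K, Pa
P0_SPCE_PA = 1017.0


def pressure_pa_to_internal(p_pa: float) -> float:
    """Convert a pressure in Pa to internal units (kJ/mol/nm^3)."""
    return float(p_pa) * PA_TO_INTERNAL


def pressure_internal_to_gpa(p_int: float) -> float:
    """Convert internal pressure units to GPa."""
    return float(p_int) * INTERNAL_TO_GPA


def density_g_cm3(total_mass_g_mol: float, volume_nm3: float) -> float:
    """Mass density in g/cm^3 from molar mass sum (g/mol) and volume (nm^3)."""
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    # g/mol / (nm^3 * N_A) -> g/cm^3 ; 1 nm^3 = 1e-21 cm^3
    return total_mass_g_mol / (volume_nm3 * N_AVOGADRO * 1.0e-21)


def volume_for_density(total_mass_g_mol: float, density_g_cm3_: float) -> float:
    """Box volume in nm^3 giving the requested density (g/cm^3)."""
    if density_g_cm3_ <= 0:
        raise ValueError("density must be positive")
    return total_mass_g_mol / (density_g_cm3_ * N_AVOGADRO * 1.0e-21)


def maxwell_boltzmann_velocities(masses: np.ndarray, T: float, rng) -> np.ndarray:
    """Draw velocities (nm/ps) from the Maxwell-Boltzmann distribution."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * T / masses)
    return rng.normal(0.0, 1.0, size=(masses.size, 3)) * sigma[:, None]
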