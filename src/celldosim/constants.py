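"""Embedded physical constants and material data.

All lengths are nm, energies keV (particle kinetics) or eV (deposits),
densities g/cm^3, unless noted otherwise.  This is the single place where
numeric physics data live; every module imports from here.
"""

from __future__ import annotations

# --- fundamental constants ------------------------------------------------
ELECTRON_MASS_KEV = 510.998950  # electron rest energy, keV
AVOGADRO = 6.02214076e23  # 1/mol
EV_TO_JOULE = 1.602176634e-19
SECONDS_PER_DAY = 86400.0

# --- element data: Z, A (g/mol) -------------------------------------------
ELEMENTS = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "S": (16, 32.06),
    "P": (15, 30.974),
    "Au": (79, 196.96657),
}

# --- default CHO cell geometry (radii in nm) -------------------------------
CELL_RADIUS_NM = 6000.0
MEMBRANE_THICKNESS_NM = 10.0
NUCLEUS_RADIUS_NM = 3300.0
N_MITOCHONDRIA = 90
MITOCHONDRION_RADIUS_NM = 463.0

# Elemental mass fractions of the cell compartments (mass percent / 100).
# All compartments are unit-density soft matter; nanoparticles are gold.
COMPOSITION_CYTOSOL = {"H": 0.1025, "C": 0.1225, "N": 0.0425, "O": 0.7325}
COMPOSITION_NUCLEUS = {
    "H": 0.1060, "C": 0.0900, "N": 0.0320, "O": 0.7420, "S": 0.0040, "P": 0.0260,
}
COMPOSITION_MITOCHONDRION = dict(COMPOSITION_NUCLEUS)
COMPOSITION_MEMBRANE = {"H": 0.1025, "C": 0.1225, "N": 0.0425, "O": 0.7325}
COMPOSITION_GOLD = {"Au": 1.0}

TISSUE_DENSITY = 1.0  # g/cm^3, all aqueous compartments
GOLD_DENSITY = 19.32  # g/cm^3

# Mean excitation energies (eV): water-equivalent media and gold.
I_TISSUE_EV = 78.0
I_GOLD_EV = 790.0

# Electron density parameter of liquid water (mol electrons per gram); all
# aqueous compartments use water stopping-power parameters regardless of
# their stored elemental composition (a <1% distinction).
Z_OVER_A_WATER = 10.0 / 18.015  # (2*1 + 8) electrons per H2O formula mass

# Radiation lengths (g/cm^2) for the Highland multiple-scattering width.
X0_WATER = 36.08
X0_GOLD = 6.46

# --- 198Au nuclide data ----------------------------------------------------
AU198_HALF_LIFE_DAYS = 2.7
AU198_ISOTOPE_MASS_U = 198.0
# beta- branches: endpoint energy keV -> branching ratio
AU198_BETA_BRANCHES = {961.0: 0.99, 285.0: 0.01}
# gamma lines: energy keV -> emission probability per decay; the two weak
# lines are tabulated only as "below 1%" in standard compilations and default
# to 0.01 here (overridable through NuclideSpec).
AU198_GAMMA_LINES = {412.0: 0.96, 676.0: 0.01, 1088.0: 0.01}
# Atomic number of the beta-decay daughter (198Hg), used by the Coulomb
# (Fermi-function) correction of the beta spectrum shape.
AU198_DAUGHTER_Z = 80

# --- photon data -----------------------------------------------------------
# Water total mass attenuation and mass energy-absorption coefficients
# (cm^2/g) at the three gamma-line energies; log-interpolated in between.
PHOTON_MU_TABLE_KEV = (412.0, 676.0, 1088.0)
PHOTON_MU_OVER_RHO = (0.1050, 0.0848, 0.0678)
PHOTON_MUEN_OVER_RHO = (0.0328, 0.0326, 0.0303)
PHOTON_E_MIN_KEV = 100.0
PHOTON_E_MAX_KEV = 2000.0


def z_over_a(mass_fractions: dict[str, float]) -> float:
    """Mean Z/A (mol electrons per gram) of a mixture by Bragg additivity."""
    return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1]
               for el, w in mass_fractions.items())
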