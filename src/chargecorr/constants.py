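"""Physical constants, unit conventions and default parameter sets.

Units used throughout the package: lengths in nm, charges in elementary
charges e, energies in kJ/mol.  The Coulomb prefactor ``COULOMB_FACTOR``
is 1/(4*pi*eps0) expressed in kJ mol^-1 nm e^-2, so that the interaction
energy of two unit charges 1 nm apart is 138.9354578 kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: 1/(4*pi*eps0) in kJ mol^-1 nm e^-2 (CODATA-consistent).
COULOMB_FACTOR = 138.9354578

#: Avogadro's constant, mol^-1 (energies are already molar, so this is
#: only needed when converting to per-particle quantities).
AVOGADRO = 6.02214076e23

#: Estimate for the radius of a water molecule, nm.  Subtracted from the
#: solute-atom/water-oxygen Lennard-Jones minimum distance to obtain the
#: atomic radius entering the dielectric-cavity construction.
WATER_PROBE_RADIUS = 0.14

#: Radius assigned to polar hydrogen atoms in the cavity construction, nm.
POLAR_H_RADIUS = 0.05

#: Relative dielectric permittivity of the SPC water model.
EPS_SPC = 66.6

#: Relative dielectric permittivity of real water at 300 K.
EPS_WATER_EXP = 78.4

#: Quadrupole-moment trace of the SPC water model relative to its single
#: van der Waals interaction site (the oxygen), e nm^2.
GAMMA_S_SPC = 0.0082

#: Molecular dipole moment of the SPC water model, e nm (0.41 e on each
#: hydrogen, O-H 0.1 nm, H-O-H 109.47 deg).
SPC_DIPOLE = 0.0506

#: SPC water geometry (nm / degrees) and partial charges (e).
SPC_OH = 0.1
SPC_HOH_DEG = 109.47
SPC_Q_O = -0.82
SPC_Q_H = 0.41


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the constants shared by all correction terms."""

    coulomb_factor: float = COULOMB_FACTOR
    avogadro: float = AVOGADRO
    water_radius_probe: float = WATER_PROBE_RADIUS
    polar_H_radius: float = POLAR_H_RADIUS

    def __post_init__(self) -> None:
        if self.coulomb_factor <= 0:
            raise ValueError("coulomb_factor must be positive")
        if self.water_radius_probe <= 0 or self.polar_H_radius <= 0:
            raise ValueError("radii must be positive")


CONSTANTS = PhysicalConstants()

# ---------------------------------------------------------------------------
# Default per-element Lennard-Jones minimum distances to the water oxygen
# (nm).  These are generic stand-in values of the order of those found in
# biomolecular united-atom force fields; they are configurable wherever a
# cavity is built and are NOT tied to any particular force-field parameter set.
# ---------------------------------------------------------------------------
DEFAULT_LJ_MIN_TABLE: dict[str, float] = {
    "C": 0.392,   # bare/aromatic carbon
    "CH3": 0.408, # united-atom methyl carbon
    "N": 0.345,
    "O": 0.330,
    "H": 0.290,   # nonpolar hydrogen
}

# ---------------------------------------------------------------------------
# Stand-in partial charge sets for the guest molecules and host functional
# groups.  They reproduce the stated net charges (+1 methylammonium,
# -1 acetate, 0 formamide, +1 methylammonium group, -1 formate group) with
# chemically sensible polarities, but are declared defaults of this package,
# not values of any specific force field.
# ---------------------------------------------------------------------------
MAM_CHARGES: dict[str, float] = {"CH3": 0.40, "N": -0.60, "H1": 0.40, "H2": 0.40, "H3": 0.40}
ACE_CHARGES: dict[str, float] = {"CH3": 0.00, "C": 0.27, "O1": -0.635, "O2": -0.635}
CHB_GROUP_CHARGES: dict[str, float] = {"C": 0.38, "O": -0.38, "N": -0.28, "H1": 0.14, "H2": 0.14}
CPOS_GROUP_CHARGES: dict[str, float] = {"N": -0.20, "H1": 0.40, "H2": 0.40, "H3": 0.40}
CNEG_GROUP_CHARGES: dict[str, float] = {"C": 0.27, "O1": -0.635, "O2": -0.635}
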