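"""Internal unit system and physical constants.

Everything in the package uses one consistent unit set:

========================  =========================
quantity                  unit
========================  =========================
length                    Angstrom (A)
time                      femtosecond (fs)
mass                      g/mol
energy                    kJ/mol
temperature               K
pressure                  atm
charge                    elementary charge (e)
dipole moment             e*A
========================  =========================

Published coarse-grained solvent parameters are frequently quoted in nm and
kJ/mol/nm^2; conversion to this unit set happens once, at the point where a
parameter is defined, never inside a kernel.
"""

import numpy as np

#: Gas constant / Boltzmann constant, kJ/(mol K).
KB = 8.314462618e-3
R_GAS = KB

#: Coulomb prefactor 1/(4 pi eps0) in kJ A / (mol e^2).
COULOMB_K = 1389.35458

#: (g/mol) * (A/fs)^2  ->  kJ/mol.
MVV_TO_KJMOL = 1.0e4

#: kJ/(mol A^3)  ->  atm.
PRESSURE_TO_ATM = 1.0e3 / (6.02214076e23 * 1.0e-30) / 101325.0

#: Debye -> e*A.
DEBYE_TO_EA = 0.208194343

#: g/cm^3 -> (g/mol)/A^3  (multiply a density by this to get mass per volume
#: in internal units); equals N_A * 1e-24.
GCM3_TO_INTERNAL = 6.02214076e23 * 1.0e-24


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Translational kinetic energy in kJ/mol."""
    return 0.5 * MVV_TO_KJMOL * float(np.sum(masses * np.sum(velocities**2, axis=1)))


def rotational_kinetic_energy(inertia: np.ndarray, ang_vel: np.ndarray) -> float:
    """Rotational kinetic energy of linear rotors (inertia in g/mol A^2)."""
    return 0.5 * MVV_TO_KJMOL * float(np.sum(inertia * np.sum(ang_vel**2, axis=1)))


def maxwell_sigma(mass: float | np.ndarray, temperature: float):
    """Per-component thermal velocity standard deviation, A/fs."""
    return np.sqrt(KB * temperature / (np.asarray(mass) * MVV_TO_KJMOL))
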