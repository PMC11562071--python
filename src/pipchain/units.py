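"""Physical constants and unit conversions.

Internal units everywhere in this package are atomic units: bohr for length,
hartree for energy, electron mass for mass, and the atomic unit of time
(~0.0242 fs) for dynamics.  Angstrom and cm^-1 are accepted and produced only
at I/O and reporting boundaries.
"""

# CODATA 2018
ANGSTROM_PER_BOHR = 0.529177210903
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

CM_PER_HARTREE = 219474.6313632
HARTREE_PER_CM = 1.0 / CM_PER_HARTREE

KCALMOL_PER_HARTREE = 627.509474063

# electron masses per unified atomic mass unit
ME_PER_AMU = 1822.888486209

# femtoseconds per atomic unit of time
FS_PER_AUT = 0.02418884326509

# Boltzmann constant, hartree per kelvin
KB_HARTREE = 3.166811563e-06

# standard atomic weights (amu); this package only handles alkanes
ATOMIC_MASS_AMU = {
    "H": 1.008,
    "C": 12.011,
}


def mass_au(element: str) -> float:
    """Mass of an element in atomic units (electron masses)."""
    return ATOMIC_MASS_AMU[element] * ME_PER_AMU
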