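"""Unit conversions.

All internal computation uses Hartree atomic units: lengths in bohr, energies
in hartree, masses in electron masses, time in au.  User-facing quantities are
angstrom, femtoseconds and kcal/mol.
"""

BOHR_TO_ANGSTROM = 0.52917721067
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

AU_TIME_TO_FS = 0.02418884254
FS_TO_AU_TIME = 1.0 / AU_TIME_TO_FS

KCALMOL_TO_HARTREE = 1.593601e-3
HARTREE_TO_KCALMOL = 1.0 / KCALMOL_TO_HARTREE

AMU_TO_ME = 1822.888486209

# hartree -> cm^-1 for angular frequencies given in au
HARTREE_TO_WAVENUMBER = 219474.6313702
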