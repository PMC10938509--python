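"""Unit conventions.

Everything internal is in Hartree atomic units: lengths in bohr, energies in
hartree, charges in units of the elementary charge, polarizabilities in bohr^3.
External files (XYZ geometries, environment descriptions) use Angstrom.
"""

#: 1 Angstrom in bohr.
BOHR_PER_ANGSTROM = 1.8897261254578281

ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR
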