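"""Unit conventions.

All internal electronic-structure quantities are in Hartree atomic units
(lengths in bohr).  User-facing file formats (XYZ, JSON site exports, cube
headers excepted per the cube standard) use Angstrom.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.52917721092
ANGSTROM_PER_BOHR = 0.52917721092


def to_bohr(x_angstrom):
    return x_angstrom * BOHR_PER_ANGSTROM


def to_angstrom(x_bohr):
    return x_bohr * ANGSTROM_PER_BOHR
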