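"""Physical constants in the package's working units (meV, Å, amu, Tesla, Kelvin)."""

from scipy import constants as _c

#: Boltzmann constant, meV / K
K_B = _c.k / _c.e * 1e3

#: Bohr magneton, meV / T
MU_B = _c.value("Bohr magneton in eV/T") * 1e3

#: hbar^2 / (2 * 1 amu), meV * Å^2  (divide by mass in amu)
HBAR2_OVER_2M = _c.hbar**2 / (2.0 * _c.atomic_mass) / _c.e * 1e3 * 1e20

#: 1 cm^-1 in meV
CM1_TO_MEV = _c.h * _c.c * 100.0 / _c.e * 1e3

#: Å per nm
ANGSTROM_PER_NM = 10.0
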