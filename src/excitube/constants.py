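"""Physical constants in the package's working units.

Working units throughout the package: length in nm, charge in elementary
charges e, energy in wavenumbers cm^-1, dipole moments in e*nm.
"""

from scipy import constants as _c

#: Coulomb energy prefactor e^2/(4*pi*eps0*h*c) expressed in cm^-1 * nm * e^-2.
#: Derivation from CODATA values: the interaction energy of two unit charges
#: at distance r is e^2/(4*pi*eps0*r) joule; dividing by h*c converts to
#: inverse meters, the factor 1e-2 to cm^-1 and 1e9 rescales r to nm.
K_COULOMB: float = (
    _c.e**2 / (4.0 * _c.pi * _c.epsilon_0) / (_c.h * _c.c) * 1e-2 * 1e9
)  # ~1.1614e4 cm^-1 nm / e^2

#: One debye in e*nm (1 D = 1e-21/c coulomb meter).
DEBYE_E_NM: float = 1e-21 / _c.c / _c.e * 1e9

#: Gas-phase excitation energy of a single C8S3 monomer, cm^-1.
E0_MONOMER_CM1: float = 19498.0

#: Minimum allowed distance between transition-charge endpoints of two
#: different molecules (nm); closer approaches are unphysical overlaps.
ENDPOINT_GUARD_NM: float = 0.1
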