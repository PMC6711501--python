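"""Physical constants and unit conversions.

Internal units throughout the package: lengths in nm, times in ns,
charges in elementary-charge units (e), fields in V/m, dipoles in e·nm.
Conversions happen only at format boundaries.
"""

#: Vacuum permittivity, F/m (CODATA).
EPSILON_0 = 8.8541878128e-12

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

#: Field magnitude of one elementary charge at 1 nm: e / (4 pi eps0 nm^2), in V/m.
#: The single hard-coded Coulomb conversion used by the field-map kernel.
COULOMB_E_NM = 1.439964e9

#: Boltzmann constant in eV/K.
K_BOLTZMANN_EV = 8.617333262e-5

#: Dipole conversion: 1 e·nm in Debye.
E_NM_TO_DEBYE = 48.0321

#: Angstrom to nanometre.
ANGSTROM_TO_NM = 0.1
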