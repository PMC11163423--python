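"""Physical constants and unit conversions shared across the package.

Every conversion between an order parameter and a quadrupolar splitting,
and between monolayer area-pressure products and molar energies, goes
through the constants defined here so the generators and the analysis
routines can never drift apart.
"""

from scipy.constants import Avogadro

#: Static quadrupolar coupling constant for a C-D bond, kHz.
#: Configurable in every routine that uses it; this is the package default.
CHI_Q_CD_KHZ = 167.0

#: 90-degree-edge quadrupolar splitting per unit |S_CD|, as a multiple of
#: chi_q: the perpendicular edges of a Pake doublet are separated by
#: (3/4) * chi_q * |S_CD|.
SPLITTING_PREFACTOR = 0.75

#: Upper physical bound on |S_CD| for a methylene segment (all-trans limit).
S_CD_MAX = 0.5

#: C-C bond projection length along the chain axis, Angstrom per segment.
L_CC_ANGSTROM = 1.27

#: 1 (A^2/molecule) * (mN/m) expressed in J/mol:
#: 1e-20 m^2 * 1e-3 N/m = 1e-23 J per molecule, times Avogadro's number.
AREA_PRESSURE_TO_J_PER_MOL = 1e-23 * Avogadro
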