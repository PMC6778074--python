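"""Physical constants and fixed model parameters (SI-derived, keV/nm working units)."""

import math

AVOGADRO = 6.02214076e23  # 1/mol
KEV_TO_JOULE = 1.602176634e-16
EV_TO_KEV = 1.0e-3
LN2 = math.log(2.0)

ELECTRON_REST_KEV = 510.99895
ALPHA_REST_KEV = 3.727379e6
FINE_STRUCTURE = 1.0 / 137.035999

FE_MOLAR_MASS_G = 55.845
WATER_DENSITY_G_CM3 = 1.0

# Core-shell nanoparticle model: 6 nm iron-oxide core, 1 nm radiolabel ring,
# polyglucose sorbitol carboxymethylether coat out to an 8.5 nm outer radius.
NP_CORE_RADIUS_NM = 3.0
NP_LABEL_INNER_NM = 3.0
NP_LABEL_OUTER_NM = 4.0
NP_OUTER_RADIUS_NM = 8.5
FE_ATOMS_PER_NP = 5874  # from the Fe5874 O8752 core stoichiometry

# Default study conditions
DEFAULT_N_NP = 500
DEFAULT_BOX_NM = 3500.0
DEFAULT_N_LABELED = 10
DEFAULT_A0_BQ = 1000.0
TRACKING_CUT_KEV = 0.01  # 10 eV
PRODUCTION_CUT_KEV = 0.01

NM_TO_CM = 1.0e-7
NM3_TO_LITER = 1.0e-24
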