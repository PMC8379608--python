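"""Physical constants and unit-conversion factors.

All public functions accept the units conventional in gene-electrotransfer
work (kV/cm, cm²/s, µg/ml, µm, mm) and convert internally; these factors
keep the conversions in one place.
"""

# CODATA 2018 exact value
ELEMENTARY_CHARGE_C = 1.602176634e-19

AVOGADRO = 6.02214076e23

# average molar mass of double-stranded DNA per base pair (g/mol)
DNA_G_PER_MOL_PER_BP = 650.0

# unit conversions
KV_PER_CM_TO_V_PER_M = 1.0e5
CM2_TO_UM2 = 1.0e8        # cm²/s -> µm²/s for diffusivities
M_TO_UM = 1.0e6
UM_TO_CM = 1.0e-4
MM_TO_UM = 1.0e3
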