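"""Physical constants and default model parameters.

Unit conventions used throughout the package: coordinates in Angstrom,
energies in kcal/mol, charges in elementary units, temperatures in Kelvin,
concentrations in molar.
"""

#: Coulomb constant, kcal*A/(mol*e^2) (AMBER convention).
COULOMB_CONSTANT = 332.0637

#: Boltzmann constant, kcal/(mol*K).
BOLTZMANN_KCAL = 0.0019872

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 298.0

#: Default interior (solute) dielectric for MM-GBSA rescoring.
DEFAULT_EPS_IN = 2.0

#: Default exterior (solvent) dielectric.
DEFAULT_EPS_OUT = 78.5

#: Intrinsic-radius offset subtracted before GB descreening, Angstrom.
GB_RADIUS_OFFSET = 0.09

#: OBC-II (igb=2) rescaling parameters.
OBC2_ALPHA = 0.8
OBC2_BETA = 0.0
OBC2_GAMMA = 2.909125

#: Default HCT descreening scale when no per-atom value is provided.
DEFAULT_GB_SCREEN = 0.8

#: Nonpolar solvation: surface tension (kcal/mol/A^2), constant offset
#: (kcal/mol), probe radius (A) and sphere-point count.
SASA_GAMMA = 0.0072
SASA_BETA = 0.0
SASA_PROBE = 1.4
SASA_POINTS = 960

#: Fluormone Pan-PPAR Green kit constants used for Cheng-Prusoff (molar).
TRACER_CONC = 5e-9
TRACER_KD = 2.8e-9
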