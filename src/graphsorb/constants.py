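"""Physical constants in the package's internal unit system.

Internal units: length Å, time ps, energy kJ/mol, mass amu, charge e,
temperature K.  In these units kinetic energy is ``0.5 * m * v**2 *
AMU_TO_INTERNAL`` with velocities in Å/ps.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 8.31446261815324e-3

#: Coulomb prefactor 1/(4 pi eps0), kJ Å / (mol e^2)
COULOMB_K = 1389.35457644382

#: 1 amu expressed in kJ/mol ps^2 / Å^2 (i.e. internal mass units)
AMU_TO_INTERNAL = 1e-2

#: Graphite carbon / protein heavy-atom joint LJ zero-crossing distance, Å
GRAPHITE_SIGMA = 3.195

#: LJ well depth for the graphite interaction, kJ/mol (stored positive;
#: the potential minimum is -GRAPHITE_EPSILON)
GRAPHITE_EPSILON = 0.439

#: Non-bonded cutoff, Å
DEFAULT_CUTOFF = 12.0

#: Graphite C-C bond length, Å
CC_BOND = 1.418

#: Graphite interlayer spacing, Å
INTERLAYER = 3.348
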