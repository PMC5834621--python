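"""Physical constants and canonical internal units.

Internal units throughout the package: nanometres for lengths, degrees for
torsion grids (radians inside numerical kernels), kJ/mol for energies and
elementary charges for partial charges.  Constants are CODATA 2018.
"""

#: Boltzmann constant times Avogadro's number, kJ mol^-1 K^-1.
KB_KJMOL = 0.008314462618

#: Coulomb constant e^2/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_KJMOL_NM = 138.935458

#: Thermochemical calorie.
KCAL_TO_KJ = 4.184

#: Angstrom to nanometre.
ANGSTROM_TO_NM = 0.1

#: Default simulation temperature (K) for the liquid-crystalline comparison.
DEFAULT_TEMPERATURE = 303.0
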