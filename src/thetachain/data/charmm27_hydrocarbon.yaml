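# Hydrocarbon (lipid tail) subset of the CHARMM27 all-atom lipid force field,
# transcribed for saturated and cis-polyunsaturated chains built from the
# aliphatic types CTL2/CTL3 (sp3 C), HAL2/HAL3 (sp3 H) and the olefinic types
# CEL1/HEL1.  Charges are the standard aliphatic/olefinic group charges of
# the lipid tails; 1-4 electrostatic interactions are scaled by 0.83, the
# modification adopted for the matching bilayer simulations.
#
# Source units here: kcal/mol and Angstrom as tabulated in the CHARMM
# distribution; the loader converts to kJ/mol and nm.  Bond/angle force
# constants follow this package's E = 1/2 k x^2 convention, i.e. they are
# twice the CHARMM K values.
energy_unit: kcal/mol
length_unit: angstrom
elec14_scale: 0.83
chain_atom_types:
  methyl_C: CTL3
  methylene_C: CTL2
  olefinic_C: CEL1
  methyl_H: HAL3
  methylene_H: HAL2
  olefinic_H: HEL1
bonds:
  - {types: [CTL3, CTL2], k: 445.0, b0: 1.528}
  - {types: [CTL2, CTL2], k: 445.0, b0: 1.530}
  - {types: [CTL3, CTL3], k: 445.0, b0: 1.530}
  - {types: [CTL2, HAL2], k: 618.0, b0: 1.111}
  - {types: [CTL3, HAL3], k: 644.0, b0: 1.111}
  - {types: [CEL1, CEL1], k: 880.0, b0: 1.340}
  - {types: [CEL1, CTL2], k: 730.0, b0: 1.502}
  - {types: [CEL1, CTL3], k: 766.0, b0: 1.504}
  - {types: [CEL1, HEL1], k: 721.0, b0: 1.100}
angles:
  - {types: [HAL3, CTL3, HAL3], k: 71.0, theta0: 108.40, k_ub: 10.80, s0: 1.80200}
  - {types: [HAL2, CTL2, HAL2], k: 71.0, theta0: 109.00, k_ub: 10.80, s0: 1.80200}
  - {types: [HAL2, CTL2, CTL2], k: 53.0, theta0: 110.10, k_ub: 45.06, s0: 2.17900}
  - {types: [HAL2, CTL2, CTL3], k: 69.2, theta0: 110.10, k_ub: 45.06, s0: 2.17900}
  - {types: [HAL3, CTL3, CTL2], k: 69.2, theta0: 110.10, k_ub: 45.06, s0: 2.17900}
  - {types: [HAL3, CTL3, CTL3], k: 75.0, theta0: 110.10, k_ub: 45.06, s0: 2.17900}
  - {types: [CTL2, CTL2, CTL2], k: 116.7, theta0: 113.60, k_ub: 22.32, s0: 2.56100}
  - {types: [CTL2, CTL2, CTL3], k: 116.0, theta0: 115.00, k_ub: 16.00, s0: 2.56100}
  - {types: [CEL1, CEL1, CTL2], k: 96.0, theta0: 123.50}
  - {types: [CEL1, CEL1, CTL3], k: 96.0, theta0: 123.50}
  - {types: [CEL1, CTL2, CTL2], k: 64.0, theta0: 112.20}
  - {types: [CEL1, CTL2, CTL3], k: 64.0, theta0: 112.20}
  - {types: [CEL1, CTL2, CEL1], k: 60.0, theta0: 114.00}
  - {types: [HEL1, CEL1, CEL1], k: 104.0, theta0: 119.50}
  - {types: [HEL1, CEL1, CTL2], k: 80.0, theta0: 116.00}
  - {types: [HEL1, CEL1, CTL3], k: 80.0, theta0: 116.00}
  - {types: [HAL2, CTL2, CEL1], k: 90.0, theta0: 111.50}
  - {types: [HAL3, CTL3, CEL1], k: 84.0, theta0: 111.50}
dihedrals:
  - types: [X, CTL2, CTL2, X]
    terms: [{K: 0.19, n: 3, phase: 0.0}]
  - types: [X, CTL2, CTL3, X]
    terms: [{K: 0.16, n: 3, phase: 0.0}]
  - types: [X, CTL3, CTL3, X]
    terms: [{K: 0.155, n: 3, phase: 0.0}]
  # cis double bond itself
  - types: [CTL2, CEL1, CEL1, CTL2]
    terms: [{K: 8.50, n: 2, phase: 180.0}]
  - types: [CTL3, CEL1, CEL1, CTL2]
    terms: [{K: 8.50, n: 2, phase: 180.0}]
  - types: [HEL1, CEL1, CEL1, HEL1]
    terms: [{K: 1.00, n: 2, phase: 180.0}]
  - types: [HEL1, CEL1, CEL1, CTL2]
    terms: [{K: 1.00, n: 2, phase: 180.0}]
  - types: [HEL1, CEL1, CEL1, CTL3]
    terms: [{K: 1.00, n: 2, phase: 180.0}]
  # allylic single bonds (vinyl-methylene)
  - types: [CEL1, CEL1, CTL2, CTL2]
    terms: [{K: 0.91, n: 1, phase: 180.0},
            {K: 0.18, n: 2, phase: 180.0},
            {K: 0.17, n: 3, phase: 180.0}]
  - types: [CEL1, CEL1, CTL2, CTL3]
    terms: [{K: 0.91, n: 1, phase: 180.0},
            {K: 0.18, n: 2, phase: 180.0},
            {K: 0.17, n: 3, phase: 180.0}]
  # divinyl (methylene-interrupted) CH2: same rotational profile adopted
  - types: [CEL1, CEL1, CTL2, CEL1]
    terms: [{K: 0.91, n: 1, phase: 180.0},
            {K: 0.18, n: 2, phase: 180.0},
            {K: 0.17, n: 3, phase: 180.0}]
  - types: [CEL1, CEL1, CTL2, HAL2]
    terms: [{K: 0.30, n: 3, phase: 180.0}]
  - types: [HEL1, CEL1, CTL2, CTL2]
    terms: [{K: 0.12, n: 3, phase: 0.0}]
  - types: [HEL1, CEL1, CTL2, CTL3]
    terms: [{K: 0.12, n: 3, phase: 0.0}]
  - types: [HEL1, CEL1, CTL2, CEL1]
    terms: [{K: 0.12, n: 3, phase: 0.0}]
  - types: [HEL1, CEL1, CTL2, HAL2]
    terms: [{K: 0.12, n: 3, phase: 0.0}]
impropers: []
lj:
  - {type: CTL2, eps: 0.0560, rmin_half: 2.010, eps_14: 0.01, rmin_half_14: 1.90}
  - {type: CTL3, eps: 0.0780, rmin_half: 2.040, eps_14: 0.01, rmin_half_14: 1.90}
  - {type: HAL2, eps: 0.0280, rmin_half: 1.3400}
  - {type: HAL3, eps: 0.0240, rmin_half: 1.3400}
  - {type: CEL1, eps: 0.0680, rmin_half: 2.090}
  - {type: HEL1, eps: 0.0310, rmin_half: 1.250}
charges:
  CTL2: -0.18
  CTL3: -0.27
  HAL2: 0.09
  HAL3: 0.09
  CEL1: -0.15
  HEL1: 0.15
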