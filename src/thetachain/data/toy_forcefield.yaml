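# Minimal toy force field for unit and property tests.
# Not a physical parameter set: constants are hand-chosen so that every term
# kind (bond, angle + Urey-Bradley, dihedral series, LJ with 1-4 variants,
# charges with scaled 1-4 electrostatics) is exercised at desk scale.
energy_unit: kJ/mol
length_unit: nm
elec14_scale: 0.83
chain_atom_types:
  methyl_C: CT3
  methylene_C: CT2
  olefinic_C: CE
  methyl_H: HT
  methylene_H: HT
  olefinic_H: HE
bonds:
  - {types: [CT2, CT2], k: 200000.0, b0: 0.153}
  - {types: [CT2, CT3], k: 200000.0, b0: 0.153}
  - {types: [CT3, CT3], k: 200000.0, b0: 0.153}
  - {types: [CT2, HT], k: 280000.0, b0: 0.111}
  - {types: [CT3, HT], k: 280000.0, b0: 0.111}
  - {types: [CE, CE], k: 380000.0, b0: 0.134}
  - {types: [CE, CT2], k: 300000.0, b0: 0.150}
  - {types: [CE, CT3], k: 300000.0, b0: 0.150}
  - {types: [CE, HE], k: 300000.0, b0: 0.110}
angles:
  - {types: [CT2, CT2, CT2], k: 500.0, theta0: 112.0, k_ub: 9000.0, s0: 0.255}
  - {types: [CT3, CT2, CT2], k: 500.0, theta0: 112.0, k_ub: 9000.0, s0: 0.255}
  - {types: [CT3, CT2, CT3], k: 500.0, theta0: 112.0}
  - {types: [HT, CT2, CT2], k: 300.0, theta0: 110.0}
  - {types: [HT, CT2, CT3], k: 300.0, theta0: 110.0}
  - {types: [HT, CT3, CT2], k: 300.0, theta0: 110.0}
  - {types: [HT, CT3, CT3], k: 300.0, theta0: 110.0}
  - {types: [HT, CT2, HT], k: 280.0, theta0: 108.0}
  - {types: [HT, CT3, HT], k: 280.0, theta0: 108.0}
  - {types: [CE, CE, CT2], k: 400.0, theta0: 123.5}
  - {types: [CE, CE, CT3], k: 400.0, theta0: 123.5}
  - {types: [CE, CT2, CT2], k: 270.0, theta0: 112.2}
  - {types: [CE, CT2, CT3], k: 270.0, theta0: 112.2}
  - {types: [CE, CT2, CE], k: 250.0, theta0: 114.0}
  - {types: [HE, CE, CE], k: 400.0, theta0: 119.5}
  - {types: [HE, CE, CT2], k: 330.0, theta0: 116.0}
  - {types: [HE, CE, CT3], k: 330.0, theta0: 116.0}
  - {types: [HT, CT2, CE], k: 370.0, theta0: 111.5}
  - {types: [HT, CT3, CE], k: 370.0, theta0: 111.5}
dihedrals:
  - types: [X, CT2, CT2, X]
    terms: [{K: 0.80, n: 3, phase: 0.0}]
  - types: [X, CT2, CT3, X]
    terms: [{K: 0.67, n: 3, phase: 0.0}]
  - types: [X, CT3, CT3, X]
    terms: [{K: 0.67, n: 3, phase: 0.0}]
  - types: [X, CE, CE, X]
    terms: [{K: 35.0, n: 2, phase: 180.0}]
  - types: [X, CE, CT2, X]
    terms: [{K: 0.50, n: 3, phase: 180.0}]
  - types: [X, CE, CT3, X]
    terms: [{K: 0.50, n: 3, phase: 180.0}]
impropers: []
lj:
  - {type: CT2, eps: 0.23, rmin_half: 0.201, eps_14: 0.042, rmin_half_14: 0.190}
  - {type: CT3, eps: 0.33, rmin_half: 0.204, eps_14: 0.042, rmin_half_14: 0.190}
  - {type: HT, eps: 0.11, rmin_half: 0.134}
  - {type: CE, eps: 0.28, rmin_half: 0.209}
  - {type: HE, eps: 0.13, rmin_half: 0.125}
charges:
  CT2: -0.18
  CT3: -0.27
  HT: 0.09
  CE: -0.15
  HE: 0.15
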