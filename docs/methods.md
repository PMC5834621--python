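# Methods

## Model

A hydrocarbon chain CH₃–(CH₂)ₐ–(CH=CH–CH₂)_d–(CH₂)_b–CH₃ with N = a+3d+b+2
backbone carbons is treated as a rigid-geometry rotor chain: all bond
lengths and bond angles sit at their force-field equilibrium values, every
*cis* double-bond torsion is frozen at 0° (0° = eclipsed throughout), and
the remaining N−1−d torsions — including the two terminal methyl spins,
which move only hydrogens — are the degrees of freedom.  The unperturbed
(Θ-state) ensemble is the canonical distribution of those torsions under the
*short-range* energy only: interactions among atoms that are near neighbours
along the chain.  Long-range (many-bonds-apart) interactions are excluded by
construction, which is what makes the model a Θ-state and not a real
single-molecule vacuum simulation.

### Structural units and term ownership

The short-range energy is carried by structural units.  Unit γ governs three
consecutive *variable* torsions (v_γ, v_{γ+1}, v_{γ+2}) — units advance over
variable torsions and skip the frozen cis bonds — and spans the carbons from
one before its first torsion bond to two past its last (plus their
hydrogens).  For a saturated chain this recovers N_f = N−3 units of six
carbons; in general N_f = (N−1−d) − 2.

Which variable torsions a force-field term feels is decided structurally,
never numerically: a pair (A, B) depends on torsion t exactly when rotating
t moves one of A, B and not the other, and the stationary atom is not on the
rotation axis; a bonded term depends on the union over its atom pairs.
Hydrogens on interior carbons are rigid in the local frame of their carbon's
two neighbours, so this bookkeeping is exact for them too.

A term is *owned* by every unit whose triple contains the term's full
dependence set and whose atom span contains its atoms.  In the tabulated
unit energies each owner weights the term by 1/(number of owners).  For
interior terms this reproduces the familiar counting rule — 1/3 for a term
depending on one of the triple's torsions, 1/2 for two, 1 for three
(`classify_term_multiplier`) — and near the chain ends, where a term can
have fewer owners, the ownership count keeps the bookkeeping exact, so the
sum of the unit grids reproduces every owned term exactly once (a tested
invariant).  Terms whose dependence set fits no triple are long-range and
appear nowhere; terms depending on no variable torsion (bond, angle,
Urey-Bradley, cis-bond dihedrals, rigid pairs) are conformation-independent
constants, dropped from grids and carried additively by the exact evaluator,
where they cancel in every Boltzmann ratio.

Non-bonded inclusion follows the force field's own convention: LJ + Coulomb
for pairs ≥ 3 bonds apart, 1–4 pairs with their special LJ parameters and
the 0.83 electrostatic scale adopted for the matching bilayer work.

### Unit-type catalogue

Units are classified by the bond-order pattern of their span plus
terminal-methyl flags.  Over the ten study chains this key yields 18
distinct types rather than the 16 of the pictorial catalogue it mirrors: the
pattern key also separates the two spans whose *edge* atom is a terminal
methyl carbon (e.g. the second unit of a saturated chain, span C1…C6) from
the interior span with the same bond pattern, because the methyl carbon's
atom type and charge genuinely change the owned energies.  The count 18 is
frozen in the tests; energetic deduplication does not rely on the catalogue
at all — grids are cached by a content hash of each unit's owned terms and
multipliers, so two units share a grid exactly when their energies are
identical.

## Tabulation

Each distinct unit's energy U_m(φ_γ, φ_{γ+1}, φ_{γ+2}) is tabulated on a
regular grid (production step 1°, package default 3.6° = 100 points/axis;
the estimator is exact for any step, see below).  Pair distances on the grid
are evaluated by composing rotations about the triple's bond axes in the
base configuration — exact for rigid geometry — with the one subtlety that a
pair may have *both* endpoints moving (a terminal methyl hydrogen under the
methyl spin and a chain atom under mid-chain torsions); such pairs are
composed on both sides.  Grids are stored float32 (accumulated in float64);
at clash points the float32 relative error is ~10⁻⁷ of values that reach
10⁶ kJ/mol, which is irrelevant after Boltzmann weighting.  2D map slices
relative to the unit's global minimum (`slice_energy_map`) reproduce the
characteristic triplet interdependence: slices at different values of the
third torsion differ.

## Equiprobable partition

The tabulated Boltzmann factor is read as a periodic piecewise-trilinear
density.  The cube is cut into n strata of equal probability along the first
axis, each stratum into n columns, each column into n states (default
n = 100, i.e. 10⁶ cells per unit).  All marginal and conditional CDFs of a
piecewise-linear density are piecewise quadratic and are inverted exactly,
segment by segment, with a numerically stable quadratic root; the
equiprobability therefore holds to solver precision (measured ~10⁻¹⁴
relative, contract 10⁻³), deterministically.  Cell location uses half-open
[lo, hi) intervals so boundary hits resolve to the upper cell.  Boundaries
crowd where the energy is low — the mean volume of the lowest-energy decile
of cells is below that of the highest decile (tested).

## Sampling and estimation

Unit 1 draws (stratum, column, state) uniformly and its three torsions
uniformly inside the cell; unit γ ≥ 2 inherits its first two torsions,
locates the containing (stratum, column) in its own partition, draws a state
and the third torsion.  The proposal density is 1/(n³L₁L₂L₃)·Π 1/(nL₃); the
1/n factors cancel in the self-normalised ratio, leaving the edge-length
product W = L₁L₂L₃ · Π_{γ≥2} L₃ with N_f + 2 factors (the published product
is written with upper limit N−3; the package uses N_f, its generalisation to
unsaturated chains).  Every generated conformation is rebuilt in Cartesian
space and its exact short-range energy U_units — all owned terms once, no
multipliers, plus the rigid-geometry constants — enters the estimator

    H̄_ω = Σ H e^{−U_units/kT} W / Σ e^{−U_units/kT} W.

Because the weights use the exact energy, the estimator is consistent for
*any* grid step and any n: those choices move only the variance (verified
directly: estimates at 3.6°/n=50 and 1.8°/n=100 agree within error).  Tests
and the packaged defaults therefore use 3.6° grids and n = 50, which keep a
full chain's preparation under ~15 s.

Numerics: importance weights are accumulated in log space with a running
maximum shift; non-finite or extreme energies are clamped at 10⁶ kJ/mol
(zero weight after exponentiation, never silently dropped, counted in the
`flagged` field).  Uniform variates are drawn from one seeded PCG64 stream
in a fixed per-conformation layout, so the compiled (numba) kernel and the
pure-numpy reference path consume identical randomness and agree to
rounding; fixed seed ⇒ bit-identical results, and results are independent of
the batch schedule.  Two statistical errors are reported: the block-average
error over 10 equal blocks and an i.i.d.-style error from the weighted
variance divided by the effective sample size (ΣW′)²/ΣW′².  At low ESS the
block error is the more honest of the two.

### Efficiency

The sequential conditional proposal approximates each unit's conditional
Boltzmann law; its overlap with the exact law decays roughly geometrically
with the number of units, so the ESS fraction falls from ~40 % for one unit
to ~0.1–0.2 % for an 18-carbon chain.  That is a variance problem, not a
bias problem, and is why the original-scale studies used ~10¹² conformations
where this package's tests use 10⁶–10⁷ (statistical errors ~10⁻³ nm).

## Validation

Three independent routes must agree on every toy fixture: the stratified
importance sampler, dense-grid quadrature of the torsion integral (periodic
trapezoid, spectrally accurate for the smooth integrands used), and a
single-torsion-update Metropolis chain.  Observed agreement is well within
3σ, including for a fixture spanning a cis double bond and for cross moments
of the joint four-torsion law of a two-unit system.  The toy systems are
real chain topologies with most torsions frozen at trans, so they exercise
the production code path, not a simplified one; what they do *not* emulate
is the weight-degeneracy of long chains, which is probed separately by the
full-chain runs and by an independent full-chain Metropolis cross-check.

## Parameters

| parameter | default | meaning |
|---|---|---|
| T | 303 K | liquid-crystalline comparison temperature |
| grid step | 1° (production), 3.6° (tests/CLI default) | tabulation resolution; variance only |
| n | 100 (production), 50 (tests) | subdivisions per axis; variance only |
| ω | task-dependent (10⁵–10⁷ in tests) | sample count |
| blocks | 10 | error estimation blocks |
| energy cap | 10⁶ kJ/mol | clamp for clashed proposals |
| elec14 scale | 0.83 | 1–4 electrostatic scaling of the adopted modification |

## Known limitations

* **Absolute values depend on parameter provenance.**  The packaged
  modified-CHARMM27 hydrocarbon file is a transcription; the authentic
  parameter set and the exact atom membership of the original unit catalogue
  are not published in machine-readable form.  With this transcription the
  package's <h>_Θ values run systematically *above* the published ones
  (≈ +0.05 nm for 16:0, growing with unsaturation), a constant-sign offset
  confirmed by the independent Metropolis route — i.e. a property of the
  energy model, not of the sampler.  Trends (decrease of <h>_Θ with d at
  fixed N) are robust to this offset and reproduce.
* Branched chains, trans double bonds and conjugated systems are out of
  scope; so are head-group chemistry and any bilayer computation — bilayer
  distances enter only as inputs to δ.
* The sampler needs at least three variable torsions (one structural unit).
* ESS degrades geometrically with chain length; production-accuracy absolute
  values for N > 22 would need either many more samples or a better
  conditional proposal.
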