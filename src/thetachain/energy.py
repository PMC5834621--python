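"""Short-range energy terms, multiplier bookkeeping and unit-energy grids.

The chain's short-range (Theta-state) energy is carried entirely by its
structural units.  A force-field term (dihedral series, or a non-bonded
LJ+Coulomb pair at >= 3 bonds separation) is *owned* by every unit whose
torsion triple contains all the variable torsions the term depends on and
whose atom span contains all the term's atoms.  In the tabulated unit
energies each owner counts the term with multiplier 1/(number of owners):
for interior terms this is the 1/3 - 1/2 - 1 scheme (one, two or three of
the triple's torsions), and the multipliers always sum to one so the grid
sum reproduces every term exactly once.  Terms whose dependence set fits no
triple are long-range by definition and excluded everywhere.

Terms that do not depend on any variable torsion (bond, angle, Urey-Bradley
at fixed geometry, dihedrals across fixed cis bonds, rigid pairs) are
conformation-independent; they are dropped from the grids and carried as a
single additive constant by the exact evaluator, which cancels in every
Boltzmann ratio.

The exact per-conformation energy U_units sums each owned term once, with
no multipliers, from true Cartesian geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KJMOL_NM
from .forcefield import ForceFieldParameters, MissingParameterError
from .geometry import build_cartesian_batch, dihedral_deg
from .topology import ChainTopology, StructuralUnit

_REF_TORSION = 137.0  # reference value for variable torsions when measuring offsets


class EnergyGridError(ValueError):
    pass


def classify_term_multiplier(dependence, unit: StructuralUnit):
    """Multiplier of a term inside one unit by the published counting rule.

    Returns 1/3, 1/2 or 1 according to whether the term depends on exactly
    one, two or three of the unit's variable torsions, or the string
    ``"constant"`` for a term that depends on none of them.  The term must
    depend on no torsion outside the unit's triple.
    """
    dep = frozenset(dependence)
    if not dep:
        return "constant"
    if not dep <= unit.triple_set:
        raise ValueError("term depends on torsions outside the unit's triple")
    return {1: 1.0 / 3.0, 2: 0.5, 3: 1.0}[len(dep)]


@dataclass
class PairTerm:
    i: int
    j: int
    sep: int
    dependence: frozenset[int]
    a_lj: float      # eps * rmin^12
    b_lj: float      # 2 * eps * rmin^6
    qq: float        # k_e * q_i * q_j * (elec14 scale when 1-4)
    owners: tuple[int, ...] = ()

    def energy(self, r2):
        inv = 1.0 / r2
        r6 = inv * inv * inv
        return (self.a_lj * r6 * r6 - self.b_lj * r6) + self.qq * np.sqrt(inv)


@dataclass
class DihedralInstance:
    quad: tuple[int, int, int, int]
    torsion: int                  # 0-based torsion index; -1 when constant
    terms: tuple                  # DihedralTerm series
    offset_deg: float             # chi = phi_torsion + offset
    dependence: frozenset[int] = frozenset()
    owners: tuple[int, ...] = ()

    def energy(self, phi_deg):
        chi = np.radians(np.asarray(phi_deg, float) + self.offset_deg)
        e = 0.0
        for t in self.terms:
            e = e + t.K * (1.0 + np.cos(t.n * chi - math.radians(t.phase)))
        return e


@dataclass
class EnergyGrid:
    """Tabulated unit energy U_m(phi_a, phi_b, phi_c) on a regular grid."""

    unit_key: str
    unit_type: str
    step: float                      # degrees
    values: np.ndarray               # (G, G, G) float32, kJ/mol
    convention: str = "0deg=eclipsed"
    provenance: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_points) * self.step

    def global_min(self) -> float:
        return float(self.values.min())

    def value_at(self, phi_a, phi_b, phi_c):
        """Nearest-node lookup with periodic wrap (degrees)."""
        g = self.n_points
        idx = [np.mod(np.rint(np.asarray(p, float) / self.step).astype(int), g)
               for p in (phi_a, phi_b, phi_c)]
        return self.values[idx[0], idx[1], idx[2]]


def boltzmann_integral(grid: EnergyGrid, temperature: float) -> float:
    """Integral of exp(-U/kT) over the torsion cube (deg^3), periodic trapezoid."""
    from .constants import KB_KJMOL
    v = grid.values.astype(float)
    rho = np.exp(-(v - v.min()) / (KB_KJMOL * temperature))
    return float(rho.sum() * grid.step ** 3 * math.exp(-v.min() / (KB_KJMOL * temperature)))


# ---------------------------------------------------------------------------
# the chain energy model
# ---------------------------------------------------------------------------

class ChainEnergyModel:
    """All short-range terms of one chain under one force field.

    Provides the per-unit owned-term lists with multipliers (grid
    tabulation), the exact per-conformation evaluator, and packed arrays for
    the compiled sampling kernel.
    """

    def __init__(self, topo: ChainTopology, params: ForceFieldParameters):
        self.topology = topo
        self.params = params
        self._ref_chain = None
        self._build_reference()
        self._enumerate_dihedrals()
        self._enumerate_pairs()
        self._collect_constants()
        self._pack_arrays()

    # -- reference geometry ------------------------------------------------
    def _build_reference(self):
        topo = self.topology
        phi = topo.torsion_vector(np.full(topo.n_variable, _REF_TORSION))
        self._ref_phi = phi
        self._ref_coords = build_cartesian_batch(topo, phi[None, :])[0]

    def _measured_dihedral(self, quad) -> float:
        X = self._ref_coords
        a, b, c, d = quad
        return float(dihedral_deg(X[a], X[b], X[c], X[d]))

    # -- term enumeration ----------------------------------------------------
    def _neighbours(self, atom: int) -> list[int]:
        out = []
        for i, j, _ in self.topology.bonds:
            if i == atom:
                out.append(j)
            elif j == atom:
                out.append(i)
        return out

    def _owners_of(self, atoms, dependence) -> tuple[int, ...]:
        dep = frozenset(dependence)
        out = []
        for u in self.topology.units:
            if dep <= u.triple_set and all(a in u.atom_span for a in atoms):
                out.append(u.gamma)
        return tuple(out)

    def _enumerate_dihedrals(self):
        topo, ff = self.topology, self.params
        self.dihedrals: list[DihedralInstance] = []
        self.const_dihedrals: list[DihedralInstance] = []
        atoms = topo.atoms
        for t in topo.torsions:
            b_idx, c_idx = topo.backbone[t.bond - 1], topo.backbone[t.bond]
            for a_idx in self._neighbours(b_idx):
                if a_idx == c_idx:
                    continue
                for d_idx in self._neighbours(c_idx):
                    if d_idx == b_idx:
                        continue
                    quad = (a_idx, b_idx, c_idx, d_idx)
                    terms = ff.dihedral(*(atoms[i].atom_type for i in quad))
                    dep = topo.term_dependence(quad)
                    chi_ref = self._measured_dihedral(quad)
                    if t.variable:
                        k = t.bond - 1
                        off = (chi_ref - self._ref_phi[k]) % 360.0
                        inst = DihedralInstance(quad, k, terms, off, dep,
                                                self._owners_of(quad, dep))
                        if not dep:
                            raise EnergyGridError(
                                f"dihedral {quad} about variable bond has no dependence")
                        self.dihedrals.append(inst)
                    else:
                        inst = DihedralInstance(quad, -1, terms, chi_ref % 360.0,
                                                dep, ())
                        if dep:
                            raise EnergyGridError(
                                f"dihedral {quad} about fixed bond depends on {dep}")
                        self.const_dihedrals.append(inst)

    def _enumerate_pairs(self):
        topo, ff = self.topology, self.params
        atoms = topo.atoms
        self.pairs: list[PairTerm] = []          # active (owned, torsion-dependent)
        self.const_pairs: list[PairTerm] = []    # rigid pairs inside a span
        self.excluded_pairs = 0                  # long-range, outside every unit
        na = topo.natoms
        in_any_span = lambda i, j: any(
            i in u.atom_span and j in u.atom_span for u in topo.units)
        for i in range(na):
            for j in range(i + 1, na):
                sep = topo.bond_separation(i, j)
                if sep < 3:
                    continue
                dep = topo.pair_dependence(i, j)
                ti, tj = atoms[i].atom_type, atoms[j].atom_type
                lj_i, lj_j = ff.lj(ti), ff.lj(tj)
                if sep == 3:
                    ei, ri = lj_i.pair_14()
                    ej, rj = lj_j.pair_14()
                    scale = ff.elec14_scale
                else:
                    ei, ri = lj_i.eps, lj_i.rmin_half
                    ej, rj = lj_j.eps, lj_j.rmin_half
                    scale = 1.0
                eps = math.sqrt(ei * ej)
                rmin = ri + rj
                qq = (COULOMB_KJMOL_NM * scale
                      * ff.charge(atoms[i].charge_class)
                      * ff.charge(atoms[j].charge_class))
                term = PairTerm(i, j, sep, dep,
                                a_lj=eps * rmin ** 12, b_lj=2.0 * eps * rmin ** 6,
                                qq=qq)
                if not dep:
                    if in_any_span(i, j):
                        self.const_pairs.append(term)
                    continue
                owners = self._owners_of((i, j), dep)
                if owners:
                    term.owners = owners
                    self.pairs.append(term)
                else:
                    self.excluded_pairs += 1

    def _collect_constants(self):
        """Conformation-independent energy: bonds, angles, UB, rigid terms."""
        topo, ff = self.topology, self.params
        X = self._ref_coords
        atoms = topo.atoms
        const = 0.0
        # bonds (zero at equilibrium by construction, kept for completeness)
        for i, j, _ in topo.bonds:
            b = ff.bond(atoms[i].atom_type, atoms[j].atom_type)
            r = float(np.linalg.norm(X[i] - X[j]))
            const += 0.5 * b.k * (r - b.b0) ** 2
        # angles + Urey-Bradley over all bonded triples
        neigh = {a.index: self._neighbours(a.index) for a in atoms}
        for b_at in range(topo.natoms):
            nb = neigh[b_at]
            for x in range(len(nb)):
                for y in range(x + 1, len(nb)):
                    i, k = nb[x], nb[y]
                    a = ff.angle(atoms[i].atom_type, atoms[b_at].atom_type,
                                 atoms[k].atom_type)
                    v1 = X[i] - X[b_at]
                    v2 = X[k] - X[b_at]
                    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    th = math.acos(max(-1.0, min(1.0, cosang)))
                    const += 0.5 * a.k * (th - math.radians(a.theta0)) ** 2
                    if a.k_ub:
                        s = float(np.linalg.norm(X[i] - X[k]))
                        const += 0.5 * a.k_ub * (s - a.s0) ** 2
        # rigid dihedrals (across fixed cis bonds)
        for inst in self.const_dihedrals:
            const += float(inst.energy(0.0))   # offset carries the fixed angle
        # rigid pairs inside spans
        for p in self.const_pairs:
            r2 = float(np.sum((X[p.i] - X[p.j]) ** 2))
            const += float(p.energy(np.array(r2)))
        self.constant_energy = const

    # -- packed arrays (exact evaluator & kernel) ---------------------------
    def _pack_arrays(self):
        self.pair_i = np.array([p.i for p in self.pairs], np.int64)
        self.pair_j = np.array([p.j for p in self.pairs], np.int64)
        self.pair_a = np.array([p.a_lj for p in self.pairs])
        self.pair_b = np.array([p.b_lj for p in self.pairs])
        self.pair_q = np.array([p.qq for p in self.pairs])
        # dihedral Fourier reduction: sum_t sum_n A cos(n phi_t) + B sin(n phi_t)
        fc: dict[tuple[int, int], list[float]] = {}
        const = 0.0
        for inst in self.dihedrals:
            for t in inst.terms:
                const += t.K
                arg = math.radians(t.n * inst.offset_deg - t.phase)
                key = (inst.torsion, t.n)
                acc = fc.setdefault(key, [0.0, 0.0])
                acc[0] += t.K * math.cos(arg)
                acc[1] -= t.K * math.sin(arg)
        keys = sorted(fc)
        self.four_t = np.array([k[0] for k in keys], np.int64)
        self.four_n = np.array([float(k[1]) for k in keys])
        self.four_a = np.array([fc[k][0] for k in keys])
        self.four_b = np.array([fc[k][1] for k in keys])
        self.dihedral_const = const

    # -- exact evaluation ----------------------------------------------------
    def exact_energy_batch(self, phi_deg: np.ndarray,
                           coords: np.ndarray | None = None,
                           include_constant: bool = True) -> np.ndarray:
        """U_units (kJ/mol) for a batch of full torsion vectors (B, N-1)."""
        phi_deg = np.atleast_2d(np.asarray(phi_deg, float))
        if coords is None:
            coords = build_cartesian_batch(self.topology, phi_deg)
        d = coords[:, self.pair_i] - coords[:, self.pair_j]
        r2 = np.sum(d * d, axis=-1)
        inv = 1.0 / r2
        r6 = inv * inv * inv
        e = np.sum(self.pair_a * r6 * r6 - self.pair_b * r6
                   + self.pair_q * np.sqrt(inv), axis=-1)
        phir = np.radians(phi_deg[:, self.four_t])
        e += np.sum(self.four_a * np.cos(self.four_n * phir)
                    + self.four_b * np.sin(self.four_n * phir), axis=-1)
        e += self.dihedral_const
        if include_constant:
            e += self.constant_energy
        return e

    def exact_energy(self, phi_deg, include_constant: bool = True) -> float:
        return float(self.exact_energy_batch(np.asarray(phi_deg, float)[None, :],
                                             include_constant=include_constant)[0])

    # -- per-unit term lists and grid tabulation ------------------------------
    def unit_owned_terms(self, gamma: int):
        """(pair terms, dihedral instances) owned by unit ``gamma`` with multipliers."""
        pairs = [(p, 1.0 / len(p.owners)) for p in self.pairs if gamma in p.owners]
        dihs = [(d, 1.0 / len(d.owners)) for d in self.dihedrals if gamma in d.owners]
        return pairs, dihs

    def unit_key(self, gamma: int) -> str:
        """Content hash of a unit's owned terms; equal keys share one grid."""
        import hashlib
        u = self.topology.units[gamma]
        lo = u.span_carbons[0]

        def label(idx: int):
            a = self.topology.atoms[idx]
            if not a.is_h:
                return ("C", a.pos - lo, 0)
            rank = self.topology.hydrogens_on(a.pos).index(idx)
            return ("H", a.pos - lo, rank)

        def tpos(t: int) -> int:
            return u.torsion_indices.index(t)

        pairs, dihs = self.unit_owned_terms(gamma)
        items = []
        for p, m in pairs:
            items.append(("pair", label(p.i), label(p.j), p.sep,
                          tuple(sorted(tpos(t) for t in p.dependence)),
                          round(p.a_lj, 12), round(p.b_lj, 12), round(p.qq, 12),
                          round(m, 12)))
        for d, m in dihs:
            items.append(("dih", tuple(label(i) for i in d.quad),
                          tpos(d.torsion), round(d.offset_deg, 9),
                          tuple((t.K, t.n, t.phase) for t in d.terms), round(m, 12)))
        payload = repr((u.unit_type, sorted(items)))
        return u.unit_type + ":" + hashlib.sha256(payload.encode()).hexdigest()[:12]

    def tabulate_unit_energy(self, gamma: int, step: float = 1.0,
                             dtype=np.float32) -> EnergyGrid:
        """Tabulate U_m over the unit's torsion triple with the given step (deg)."""
        topo = self.topology
        u = topo.units[gamma]
        g = 360.0 / step
        if abs(g - round(g)) > 1e-9:
            raise EnergyGridError(f"step {step} must divide 360")
        G = int(round(g))
        ang = np.radians(np.arange(G) * step)
        cosv, sinv = np.cos(ang), np.sin(ang)

        # base geometry: triple torsions at 0, other variables at trans
        base_var = np.full(topo.n_variable, 180.0)
        for t in u.torsion_indices:
            base_var[topo.variable.index(t)] = 0.0
        phi0 = topo.torsion_vector(base_var)
        X0 = build_cartesian_batch(topo, phi0[None, :])[0]

        axes = {}
        for t in u.torsion_indices:
            a0 = X0[topo.backbone[t]]
            a1 = X0[topo.backbone[t + 1]]
            uvec = a1 - a0
            uvec = uvec / np.linalg.norm(uvec)
            axes[t] = (a0, uvec * self._rotation_sign(t, phi0, X0, a0, uvec))

        def rot_apply(t, V, c, s):
            """Rodrigues rotation of points V (..., 3) about torsion t's axis,
            broadcasting rotation angles with trig arrays c, s shaped (G,)."""
            p, uv = axes[t]
            W = V - p
            dot = W @ uv
            cross = np.cross(np.broadcast_to(uv, W.shape), W)
            cN = c.reshape((G,) + (1,) * W.ndim)
            sN = s.reshape((G,) + (1,) * W.ndim)
            out = (cN * W[None, ...] - sN * cross[None, ...]
                   + (1.0 - cN) * dot[None, ..., None] * uv)
            return out + p

        tpos = {t: i for i, t in enumerate(u.torsion_indices)}
        U = np.zeros((G, G, G))

        pairs, dihs = self.unit_owned_terms(gamma)
        for d, mult in dihs:
            e = d.energy(np.arange(G) * step)
            shape = [1, 1, 1]
            shape[tpos[d.torsion]] = G
            U += mult * e.reshape(shape)

        for p, mult in pairs:
            S = sorted(p.dependence)
            # split S by which endpoint each torsion moves; at most one element
            # (a terminal methyl spin) can move the other endpoint
            mv0 = topo._move_cache[S[-1]]
            B_at = p.i if p.i in mv0 else p.j
            A_at = p.j if B_at == p.i else p.i
            S_B = [t for t in S if B_at in topo._move_cache[t]]
            S_A = [t for t in S if t not in S_B]
            if len(S_A) > 1:
                raise EnergyGridError("pair with two independently moving ends")
            # B composed over S_B, innermost (largest) rotation first;
            # resulting axes are S_B in ascending order
            V = X0[B_at]
            for t in sorted(S_B, reverse=True)[:-1]:
                V = rot_apply(t, V, cosv, sinv)
            if S_A:
                # both endpoints move (one is a terminal methyl hydrogen):
                # broadcast |PA - PB|^2 via dot products
                tm = S_A[0]
                PA = rot_apply(tm, X0[A_at], cosv, sinv)        # (G, 3)
                a2 = np.sum(PA * PA, axis=-1)
                if S_B:
                    PB = rot_apply(min(S_B), V, cosv, sinv)     # S_B axes + (3,)
                    v2 = np.sum(PB * PB, axis=-1)
                    cross_term = np.tensordot(PA, np.moveaxis(PB, -1, 0),
                                              axes=(1, 0))
                    d2 = (a2.reshape((G,) + (1,) * (PB.ndim - 1))
                          + v2[None, ...] - 2.0 * cross_term)
                    if tm > min(S_B):
                        d2 = np.moveaxis(d2, 0, -1)
                        axes_order = sorted(S_B) + [tm]
                    else:
                        axes_order = [tm] + sorted(S_B)
                else:
                    B0 = X0[B_at]
                    d2 = a2 + B0 @ B0 - 2.0 * (PA @ B0)
                    axes_order = [tm]
            else:
                # A fixed; apply the outermost rotation analytically
                t0 = min(S_B)
                pvt, uv = axes[t0]
                Ap = X0[A_at] - pvt
                Vp = V - pvt
                cross_u = np.cross(np.broadcast_to(uv, Vp.shape), Vp)
                dotA = Ap @ uv
                dotV = Vp @ uv
                AdotV = Vp @ Ap
                Adotcross = cross_u @ Ap
                a2 = Ap @ Ap
                v2 = np.sum(Vp * Vp, axis=-1)
                c0 = cosv.reshape((G,) + (1,) * (len(S_B) - 1))
                s0 = sinv.reshape((G,) + (1,) * (len(S_B) - 1))
                d2 = a2 + v2 - 2.0 * (c0 * AdotV - s0 * Adotcross
                                      + (1.0 - c0) * dotA * dotV)
                axes_order = sorted(S_B)
            e = mult * p.energy(np.maximum(d2, 1e-12))
            # d2 axes follow axes_order (ascending); embed into the 3D grid
            perm_axes = [tpos[t] for t in axes_order]
            if perm_axes != sorted(perm_axes):
                e = np.transpose(e, np.argsort(perm_axes))
            idx = tuple(slice(None) if i in perm_axes else None for i in range(3))
            U += e[idx]

        if not np.all(np.isfinite(U)):
            raise EnergyGridError(f"non-finite energy in unit {gamma} grid")
        return EnergyGrid(
            unit_key=self.unit_key(gamma), unit_type=u.unit_type, step=step,
            values=U.astype(dtype),
            provenance={"forcefield": self.params.content_hash(),
                        "chain": topo.spec.name, "gamma": gamma})

    def _rotation_sign(self, t: int, phi0: np.ndarray, X0: np.ndarray,
                       a0: np.ndarray, uvec: np.ndarray) -> float:
        """Orient the rotation axis so +delta rotation equals +delta torsion."""
        topo = self.topology
        delta = 23.0
        phi1 = phi0.copy()
        phi1[t] = (phi1[t] + delta) % 360.0
        X1 = build_cartesian_batch(topo, phi1[None, :])[0]
        mv = topo._move_cache[t]
        probe = next(iter(mv))
        c, s = math.cos(math.radians(delta)), math.sin(math.radians(delta))
        W = X0[probe] - a0
        dot = float(W @ uvec)
        for sign in (1.0, -1.0):
            uu = uvec * sign
            cr = np.cross(uu, W)
            pred = c * W - s * cr + (1 - c) * dot * sign * uu + a0
            if np.linalg.norm(pred - X1[probe]) < 1e-8:
                return sign
        raise EnergyGridError("could not orient torsion rotation axis")


def tabulate_unit_energy(unit: StructuralUnit, model: ChainEnergyModel,
                         step: float = 1.0) -> EnergyGrid:
    """Free-function front-end mirroring the model method."""
    return model.tabulate_unit_energy(unit.gamma, step)


def slice_energy_map(grid: EnergyGrid, fixed_axis: int, fixed_value: float) -> np.ndarray:
    """2D map at one fixed torsion, measured from the grid's global minimum.

    ``fixed_axis`` is 1, 2 or 3; ``fixed_value`` must lie on the grid.
    """
    if fixed_axis not in (1, 2, 3):
        raise EnergyGridError("fixed_axis must be 1, 2 or 3")
    idxf = fixed_value / grid.step
    if abs(idxf - round(idxf)) > 1e-9:
        raise EnergyGridError(f"{fixed_value} deg is not on the {grid.step} deg grid")
    idx = int(round(idxf)) % grid.n_points
    sl = [slice(None)] * 3
    sl[fixed_axis - 1] = idx
    return grid.values[tuple(sl)].astype(float) - grid.global_min()
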