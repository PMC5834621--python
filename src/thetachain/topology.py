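"""Explicit-hydrogen chain topologies and structural-unit decomposition.

A chain of N backbone carbons has N-1 torsions phi_1..phi_(N-1), one per
backbone bond (bond k joins carbons Ck and C(k+1)).  Torsion 1 and torsion
N-1 are the terminal methyl spins (they move only methyl hydrogens); cis
double-bond torsions are fixed at 0 deg (0 deg = eclipsed throughout the
package).  The remaining torsions are the variable degrees of freedom.

The chain is decomposed into structural units: unit gamma governs three
consecutive *variable* torsions (v_g, v_(g+1), v_(g+2)); consecutive units
share two torsions.  For a saturated chain this gives N_f = N - 3 units; in
general N_f = (number of variable torsions) - 2.  Each unit owns the chain
fragment spanning carbons [k1 - 1, k3 + 2] (k1/k3 the unit's first/last
torsion bond) plus attached hydrogens, and is typed by the bond-order
pattern of that span together with terminal-methyl flags.

Geometry is rigid apart from torsions: bonds and angles sit at their
force-field equilibrium values.  Every atom has a z-matrix entry; hydrogens
on interior carbons are placed with a constant dihedral in the local frame
(C(m-1), Cm, C(m+1)), so their positions relative to both carbon neighbours
never change when torsions rotate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chainspec import ChainSpec, ChainSpecError, parse_chain_spec, STUDY_CHAINS
from .forcefield import ForceFieldParameters, MissingParameterError

#: roles that the force field's ``chain_atom_types`` section must map
REQUIRED_ROLES = ("methyl_C", "methylene_C", "olefinic_C",
                  "methyl_H", "methylene_H", "olefinic_H")


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    index: int
    element: str          # "C" or "H"
    atom_type: str
    charge_class: str
    pos: int              # 1-based backbone position (H: position of parent C)
    is_h: bool


@dataclass(frozen=True)
class TorsionInfo:
    bond: int                     # 1-based backbone bond index k
    quad: tuple[int, int, int, int]   # atom indices defining the dihedral
    variable: bool
    fixed_value: float = 0.0      # degrees, used when not variable


@dataclass
class StructuralUnit:
    gamma: int                         # 0-based unit index along the chain
    torsion_indices: tuple[int, int, int]  # 0-based torsion (= bond-1) indices
    span_carbons: tuple[int, int]      # 1-based inclusive carbon range
    atom_span: frozenset[int]
    unit_type: str

    @property
    def triple_set(self) -> frozenset[int]:
        return frozenset(self.torsion_indices)


def _span_for_triple(triple: tuple[int, int, int], N: int) -> tuple[int, int]:
    """Carbon range [k1-1, k3+2] (1-based, clipped) for 0-based torsions."""
    k1, k3 = triple[0] + 1, triple[2] + 1
    return max(1, k1 - 1), min(N, k3 + 2)


def _pattern(spec: ChainSpec, span: tuple[int, int]) -> str:
    lo, hi = span
    doubles = set(spec.double_bond_positions)
    orders = "".join("2" if b in doubles else "1" for b in range(lo, hi))
    lm = "M" if lo == 1 else "-"
    rm = "M" if hi == spec.N else "-"
    return f"u[{lm}{orders}{rm}]"


def variable_torsion_indices(spec: ChainSpec) -> list[int]:
    """0-based indices of variable torsions (all bonds except cis doubles)."""
    doubles = set(spec.double_bond_positions)
    return [k - 1 for k in range(1, spec.N) if k not in doubles]


def unit_triples(spec: ChainSpec) -> list[tuple[int, int, int]]:
    var = variable_torsion_indices(spec)
    if len(var) < 3:
        raise TopologyError(f"{spec.name}: fewer than 3 variable torsions")
    return [tuple(var[g:g + 3]) for g in range(len(var) - 2)]


def unit_types_for_spec(spec: ChainSpec) -> list[str]:
    """Unit-type key sequence from the chain formula alone (no force field)."""
    return [_pattern(spec, _span_for_triple(t, spec.N)) for t in unit_triples(spec)]


def unit_type_catalogue(names=STUDY_CHAINS) -> dict[str, list[str]]:
    """All distinct unit types over a chain set, mapped to the chains using them."""
    cat: dict[str, list[str]] = {}
    for name in names:
        spec = parse_chain_spec(name)
        for ut in set(unit_types_for_spec(spec)):
            cat.setdefault(ut, []).append(spec.name)
    return {k: sorted(set(v)) for k, v in sorted(cat.items())}


def reversed_unit_type(ut: str) -> str:
    """The type a unit maps to when the chain direction is reversed."""
    body = ut[2:-1]
    lm, orders, rm = body[0], body[1:-1], body[-1]
    return f"u[{rm}{orders[::-1]}{lm}]"


# ---------------------------------------------------------------------------
# hydrogen local geometry
# ---------------------------------------------------------------------------

def _dihedral_deg(p0, p1, p2, p3):
    """Signed dihedral (degrees, 0 = eclipsed/cis) of the four points."""
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))


def _h_frame_entries(theta_prev_deg: float, theta_next_deg: float,
                     theta_ccc_deg: float, n_h: int) -> list[tuple[float, float]]:
    """(angle to previous carbon, constant dihedral) for H's on an interior carbon.

    The local frame places C(m-1) and C(m+1) at the equilibrium backbone
    angle; hydrogens satisfy both H-C-C equilibrium angles exactly when a
    real solution exists (sp3, two H symmetric out of plane; sp2, one H in
    plane, direction renormalised).
    """
    t1, t2 = math.radians(theta_prev_deg), math.radians(theta_next_deg)
    tc = math.radians(theta_ccc_deg)
    n1 = np.array([1.0, 0.0, 0.0])
    n2 = np.array([math.cos(tc), math.sin(tc), 0.0])
    c = math.cos(tc)
    det = 1.0 - c * c
    alpha = (math.cos(t1) - c * math.cos(t2)) / det
    beta = (math.cos(t2) - c * math.cos(t1)) / det
    h_in = alpha * n1 + beta * n2
    r2 = float(h_in @ h_in)
    out: list[tuple[float, float]] = []
    cm = np.zeros(3)
    cprev = n1   # unit distances suffice for angle/dihedral measurement
    cnext = n2
    if n_h == 1:
        h = h_in / math.sqrt(r2)
        ang = math.degrees(math.acos(float(np.clip(h @ n1, -1, 1))))
        dih = _dihedral_deg(h, cm, cprev, cnext)
        out.append((ang, dih))
    else:
        gamma2 = 1.0 - r2
        if gamma2 <= 0:
            raise TopologyError("hydrogen angle constraints have no real solution")
        g = math.sqrt(gamma2)
        for sgn in (+1.0, -1.0):
            h = h_in + sgn * g * np.array([0.0, 0.0, 1.0])
            ang = math.degrees(math.acos(float(np.clip(h @ n1, -1, 1))))
            dih = _dihedral_deg(h, cm, cprev, cnext)
            out.append((ang, dih))
    return out


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

@dataclass
class ChainTopology:
    spec: ChainSpec
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]          # (i, j, order)
    backbone: list[int]                        # atom index of C1..CN
    torsions: list[TorsionInfo]                # length N-1, chain order
    variable: list[int]                        # 0-based variable torsion indices
    units: list[StructuralUnit]
    # z-matrix (per atom): refs, bond length (nm), angle (rad),
    # torsion index (>=0: dihedral = phi[tor] + off; -1: constant off;
    # -2: no dihedral, one of the first three atoms), offset (rad)
    z_p1: np.ndarray = field(repr=False, default=None)
    z_p2: np.ndarray = field(repr=False, default=None)
    z_p3: np.ndarray = field(repr=False, default=None)
    z_bond: np.ndarray = field(repr=False, default=None)
    z_angle: np.ndarray = field(repr=False, default=None)
    z_tor: np.ndarray = field(repr=False, default=None)
    z_off: np.ndarray = field(repr=False, default=None)

    @property
    def N(self) -> int:
        return self.spec.N

    @property
    def natoms(self) -> int:
        return len(self.atoms)

    @property
    def n_f(self) -> int:
        return len(self.units)

    @property
    def n_variable(self) -> int:
        return len(self.variable)

    def torsion_vector(self, variable_values) -> np.ndarray:
        """Full phi vector (degrees) from values of the variable torsions."""
        variable_values = np.asarray(variable_values, float)
        if variable_values.shape[-1] != self.n_variable:
            raise ValueError(f"expected {self.n_variable} variable torsions")
        phi = np.zeros(variable_values.shape[:-1] + (self.N - 1,))
        for i, t in enumerate(self.torsions):
            if not t.variable:
                phi[..., i] = t.fixed_value
        phi[..., self.variable] = variable_values
        return phi

    # -- structural dependence machinery ----------------------------------
    def moves(self, torsion_idx: int) -> frozenset[int]:
        """Atoms whose position changes when torsion ``torsion_idx`` rotates."""
        k = torsion_idx + 1  # 1-based bond
        N = self.N
        out = set()
        if k == 1:
            return frozenset(a.index for a in self.atoms if a.is_h and a.pos == 1)
        if k == N - 1:
            return frozenset(a.index for a in self.atoms if a.is_h and a.pos == N)
        for a in self.atoms:
            if a.is_h:
                if 2 <= a.pos <= N - 1 and a.pos >= k + 1:
                    out.add(a.index)
                elif a.pos == N:
                    out.add(a.index)
            elif a.pos >= k + 2:
                out.add(a.index)
        return frozenset(out)

    def pair_dependence(self, i: int, j: int) -> frozenset[int]:
        """Variable torsions on which the distance |r_i - r_j| depends."""
        out = set()
        for t in self.variable:
            mv = self._move_cache[t]
            ai, aj = i in mv, j in mv
            if ai == aj:
                continue
            stationary = j if ai else i
            a = self.atoms[stationary]
            k = t + 1
            if (not a.is_h) and a.pos in (k, k + 1):
                continue  # stationary atom on the rotation axis
            out.add(t)
        return frozenset(out)

    def term_dependence(self, atom_indices) -> frozenset[int]:
        """Variable torsions a bonded term's value depends on."""
        idx = list(atom_indices)
        out: set[int] = set()
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                out |= self.pair_dependence(idx[i], idx[j])
        return frozenset(out)

    def bond_separation(self, i: int, j: int) -> int:
        ai, aj = self.atoms[i], self.atoms[j]
        return abs(ai.pos - aj.pos) + int(ai.is_h) + int(aj.is_h)

    def hydrogens_on(self, pos: int) -> list[int]:
        return [a.index for a in self.atoms if a.is_h and a.pos == pos]

    def report(self) -> str:
        """Plain-text topology dump (atoms, bonds, torsions, units)."""
        L = [f"chain {self.spec.name}: {self.natoms} atoms "
             f"({self.N} C, {self.natoms - self.N} H), "
             f"{len(self.torsions)} torsions ({self.n_variable} variable), "
             f"N_f = {self.n_f}"]
        L.append("atoms:")
        for a in self.atoms:
            L.append(f"  {a.index:3d} {a.element} {a.atom_type:6s} q-class "
                     f"{a.charge_class:6s} C{a.pos}")
        L.append("torsions:")
        for t in self.torsions:
            kind = "variable" if t.variable else f"fixed {t.fixed_value:g} deg"
            L.append(f"  phi_{t.bond} about C{t.bond}-C{t.bond + 1}: {kind}")
        L.append("units:")
        for u in self.units:
            ks = ",".join(str(i + 1) for i in u.torsion_indices)
            L.append(f"  gamma={u.gamma + 1} {u.unit_type} torsions phi({ks}) "
                     f"span C{u.span_carbons[0]}..C{u.span_carbons[1]}")
        return "\n".join(L)


def build_topology(spec: ChainSpec | str, params: ForceFieldParameters) -> ChainTopology:
    """Build the explicit-hydrogen rigid-geometry topology of a chain."""
    if isinstance(spec, str):
        spec = parse_chain_spec(spec)
    roles = params.chain_atom_types
    for r in REQUIRED_ROLES:
        if r not in roles:
            raise MissingParameterError(f"force field lacks chain_atom_types[{r!r}]")
    N = spec.N
    doubles = set(spec.double_bond_positions)
    sp2 = set()
    for p in doubles:
        sp2.update((p, p + 1))

    def carbon_role(m: int) -> str:
        if m in (1, N):
            return "methyl_C"
        return "olefinic_C" if m in sp2 else "methylene_C"

    def h_role(m: int) -> str:
        if m in (1, N):
            return "methyl_H"
        return "olefinic_H" if m in sp2 else "methylene_H"

    atoms: list[Atom] = []
    for m in range(1, N + 1):
        t = roles[carbon_role(m)]
        atoms.append(Atom(m - 1, "C", t, t, m, False))
    backbone = list(range(N))

    h_of: dict[int, list[int]] = {}
    for m in range(1, N + 1):
        n_h = 3 if m in (1, N) else (1 if m in sp2 else 2)
        t = roles[h_role(m)]
        h_of[m] = []
        for _ in range(n_h):
            idx = len(atoms)
            atoms.append(Atom(idx, "H", t, t, m, True))
            h_of[m].append(idx)

    bonds: list[tuple[int, int, int]] = []
    for k in range(1, N):
        bonds.append((k - 1, k, 2 if k in doubles else 1))
    for m, hs in h_of.items():
        for h in hs:
            bonds.append((m - 1, h, 1))

    # torsions
    torsions: list[TorsionInfo] = []
    for k in range(1, N):
        if k == 1:
            quad = (h_of[1][0], 0, 1, 2)
        elif k == N - 1:
            quad = (N - 3, N - 2, N - 1, h_of[N][0])
        else:
            quad = (k - 2, k - 1, k, k + 1)
        torsions.append(TorsionInfo(bond=k, quad=quad, variable=k not in doubles,
                                    fixed_value=0.0))
    variable = [t.bond - 1 for t in torsions if t.variable]

    # units (a chain with fewer than three variable torsions has none and
    # cannot be sampled, but its geometry and energies remain usable)
    try:
        triples = unit_triples(spec)
    except TopologyError:
        triples = []
    units: list[StructuralUnit] = []
    for g, tri in enumerate(triples):
        lo, hi = _span_for_triple(tri, N)
        span = set(range(lo - 1, hi))
        for m in range(lo, hi + 1):
            if lo <= m <= hi:
                span.update(h_of[m])
        units.append(StructuralUnit(
            gamma=g, torsion_indices=tri, span_carbons=(lo, hi),
            atom_span=frozenset(span), unit_type=_pattern(spec, (lo, hi))))

    topo = ChainTopology(spec=spec, atoms=atoms, bonds=bonds, backbone=backbone,
                         torsions=torsions, variable=variable, units=units)

    # ---- z-matrix ---------------------------------------------------------
    na = len(atoms)
    z_p1 = np.full(na, -1, np.int64)
    z_p2 = np.full(na, -1, np.int64)
    z_p3 = np.full(na, -1, np.int64)
    z_bond = np.zeros(na)
    z_angle = np.zeros(na)
    z_tor = np.full(na, -2, np.int64)
    z_off = np.zeros(na)

    ctype = [atoms[m - 1].atom_type for m in range(1, N + 1)]

    def b0(i, j):
        return params.bond(atoms[i].atom_type, atoms[j].atom_type).b0

    def th0(i, j, k):
        return params.angle(atoms[i].atom_type, atoms[j].atom_type,
                            atoms[k].atom_type).theta0

    # backbone
    z_bond[1] = b0(0, 1)
    z_p1[1] = 0
    z_bond[2] = b0(1, 2)
    z_angle[2] = math.radians(th0(0, 1, 2))
    z_p1[2], z_p2[2] = 1, 0
    for m in range(4, N + 1):
        i = m - 1
        z_p1[i], z_p2[i], z_p3[i] = m - 2, m - 3, m - 4
        z_bond[i] = b0(m - 2, i)
        z_angle[i] = math.radians(th0(m - 3, m - 2, i))
        z_tor[i] = m - 3          # torsion phi_(m-2), 0-based m-3
        z_off[i] = 0.0

    # hydrogens
    for m in range(1, N + 1):
        hs = h_of[m]
        htype = atoms[hs[0]].atom_type
        bh = params.bond(ctype[m - 1], htype).b0
        if m == 1:
            ang = math.radians(params.angle(htype, ctype[0], ctype[1]).theta0)
            for n, h in enumerate(hs):
                z_p1[h], z_p2[h], z_p3[h] = 0, 1, 2
                z_bond[h], z_angle[h] = bh, ang
                z_tor[h], z_off[h] = 0, math.radians(120.0 * n)
        elif m == N:
            ang = math.radians(params.angle(htype, ctype[N - 1], ctype[N - 2]).theta0)
            for n, h in enumerate(hs):
                z_p1[h], z_p2[h], z_p3[h] = N - 1, N - 2, N - 3
                z_bond[h], z_angle[h] = bh, ang
                z_tor[h], z_off[h] = N - 2, math.radians(120.0 * n)
        else:
            tprev = params.angle(htype, ctype[m - 1], ctype[m - 2]).theta0
            tnext = params.angle(htype, ctype[m - 1], ctype[m]).theta0
            tccc = params.angle(ctype[m - 2], ctype[m - 1], ctype[m]).theta0
            entries = _h_frame_entries(tprev, tnext, tccc, len(hs))
            for (ang, dih), h in zip(entries, hs):
                z_p1[h], z_p2[h], z_p3[h] = m - 1, m - 2, m
                z_bond[h], z_angle[h] = bh, math.radians(ang)
                z_tor[h], z_off[h] = -1, math.radians(dih)

    topo.z_p1, topo.z_p2, topo.z_p3 = z_p1, z_p2, z_p3
    topo.z_bond, topo.z_angle, topo.z_tor, topo.z_off = z_bond, z_angle, z_tor, z_off
    topo._move_cache = {t: topo.moves(t) for t in range(N - 1)}
    return topo


def decompose_units(topo: ChainTopology) -> list[StructuralUnit]:
    """The ordered structural-unit sequence of a built topology."""
    return list(topo.units)
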