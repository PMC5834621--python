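"""Equiprobable parallelepiped decomposition of a unit's torsion cube.

The tabulated Boltzmann factor exp(-U_m/kT) is read as a periodic
piecewise-trilinear density on the (phi_a, phi_b, phi_c) cube.  The cube is
cut into n strata of equal probability along the first axis (inverse of the
marginal CDF), every stratum into n equal-probability columns along the
second axis, and every column into n equal-probability states along the
third, giving n^3 cells that all carry Boltzmann weight Z_m/n^3.  Because
the density is piecewise linear along each axis, every CDF is piecewise
quadratic and is inverted exactly segment by segment, so the construction
is deterministic and the equiprobability holds to solver precision.

Boundaries crowd where the energy is low: low-energy cells are small, so
uniform cell sampling plus the edge-length weight W reproduces Boltzmann
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJMOL
from .energy import EnergyGrid


class PartitionError(ValueError):
    pass


@dataclass
class EquiprobablePartition:
    unit_key: str
    temperature: float
    n: int
    strata: np.ndarray                 # (n+1,) degrees
    columns: np.ndarray                # (n, n+1)
    states: np.ndarray                 # (n, n, n+1)
    z_scaled: float                    # integral of exp(-(U-Umin)/kT), deg^3
    u_shift: float                     # Umin (kJ/mol) taken out of z_scaled
    provenance: dict = field(default_factory=dict)

    def cell_probability_target(self) -> float:
        """The common scaled Boltzmann integral of every cell, Z/n^3."""
        return self.z_scaled / self.n ** 3


# ---------------------------------------------------------------------------
# piecewise-linear integral helpers (nodes at i*s, i = 0..G, wrapped)
# ---------------------------------------------------------------------------

def _cum_nodes(f: np.ndarray, s: float) -> np.ndarray:
    """Cumulative integral at the nodes for node values f (G+1, ...)."""
    seg = 0.5 * (f[:-1] + f[1:]) * s
    out = np.zeros_like(f)
    np.cumsum(seg, axis=0, out=out[1:])
    return out


def _cum_at(f: np.ndarray, F: np.ndarray, s: float, x: float) -> np.ndarray:
    """Cumulative integral of the linear interpolant at scalar x (broadcasts)."""
    G = f.shape[0] - 1
    i = min(int(x // s), G - 1)
    dx = x - i * s
    return F[i] + f[i] * dx + (f[i + 1] - f[i]) * dx * dx / (2.0 * s)


def _segment_integral(f: np.ndarray, s: float, a: float, b: float) -> np.ndarray:
    """Exact integral of the linear interpolant of f over [a, b]."""
    F = _cum_nodes(f, s)
    return _cum_at(f, F, s, b) - _cum_at(f, F, s, a)


def _invert_cdf(f: np.ndarray, s: float, n: int, lo: float, hi: float) -> np.ndarray:
    """Boundaries splitting [lo, hi] into n equal-probability parts.

    f holds node values (G+1,) of a non-negative piecewise-linear density on
    [0, 360]; the returned n+1 boundaries include lo and hi exactly.
    """
    F = _cum_nodes(f, s)
    Flo = _cum_at(f, F, s, lo)
    Fhi = _cum_at(f, F, s, hi)
    total = Fhi - Flo
    if total <= 0:
        raise PartitionError("zero probability mass in interval")
    out = np.empty(n + 1)
    out[0], out[n] = lo, hi
    targets = Flo + total * np.arange(1, n) / n
    idx = np.searchsorted(F, targets, side="right") - 1
    np.clip(idx, 0, f.shape[0] - 2, out=idx)
    for m, (q, i) in enumerate(zip(targets, idx), start=1):
        # solve f_i dx + (f_{i+1}-f_i) dx^2/(2s) = q - F_i on segment i
        r = q - F[i]
        fi = f[i]
        df = (f[i + 1] - f[i]) / s
        if abs(df) * s < 1e-14 * max(fi, 1e-300):
            dx = r / fi
        else:
            disc = fi * fi + 2.0 * df * r
            dx = 2.0 * r / (fi + np.sqrt(max(disc, 0.0)))
        out[m] = i * s + min(max(dx, 0.0), s)
    # guard monotonicity against roundoff
    return np.maximum.accumulate(out)


def _wrap(a: np.ndarray, axis: int) -> np.ndarray:
    first = np.take(a, [0], axis=axis)
    return np.concatenate([a, first], axis=axis)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_equiprobable_partition(grid: EnergyGrid, temperature: float,
                                 n: int = 100) -> EquiprobablePartition:
    """Build the n x n x n equiprobable decomposition of one unit's cube."""
    if temperature <= 0:
        raise PartitionError("temperature must be positive")
    if n < 1:
        raise PartitionError("n must be >= 1")
    U = grid.values.astype(np.float64)
    if not np.all(np.isfinite(U)):
        raise PartitionError("energy grid contains non-finite values")
    s = grid.step
    umin = float(U.min())
    rho = np.exp(-(U - umin) / (KB_KJMOL * temperature))

    # axis-1 marginal (exact for the trilinear density: periodic sums)
    f1 = _wrap(rho.sum(axis=(1, 2)) * s * s, 0)
    z = float(rho.sum() * s ** 3)
    strata = _invert_cdf(f1, s, n, 0.0, 360.0)

    rho12 = _wrap(_wrap(rho.sum(axis=2) * s, 0), 1)      # (G+1, G+1) nodes
    rho3 = _wrap(_wrap(_wrap(rho, 0), 1), 2)             # (G+1, G+1, G+1)

    columns = np.empty((n, n + 1))
    states = np.empty((n, n, n + 1))
    for i in range(n):
        a, b = strata[i], strata[i + 1]
        g2 = _segment_integral(rho12, s, a, b)           # (G+1,) phi_b nodes
        columns[i] = _invert_cdf(g2, s, n, 0.0, 360.0)
        # phi_1-integrated density on (phi_b, phi_c) nodes for this stratum
        A = _segment_integral(rho3, s, a, b)             # (G+1, G+1)
        FA = _cum_nodes(A, s)                            # cumulative along phi_b
        for j in range(n):
            c, d = columns[i, j], columns[i, j + 1]
            h = _cum_at(A, FA, s, d) - _cum_at(A, FA, s, c)   # (G+1,) phi_c
            states[i, j] = _invert_cdf(h, s, n, 0.0, 360.0)
    part = EquiprobablePartition(
        unit_key=grid.unit_key, temperature=temperature, n=n,
        strata=strata, columns=columns, states=states,
        z_scaled=z, u_shift=umin,
        provenance=dict(grid.provenance, step=s))
    _check_edges(part)
    return part


def _check_edges(part: EquiprobablePartition) -> None:
    for name, b in (("strata", part.strata), ("columns", part.columns),
                    ("states", part.states)):
        d = np.diff(b, axis=-1)
        if not np.all(d > 0):
            raise PartitionError(f"non-increasing {name} boundaries")


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def locate_cell(part: EquiprobablePartition, phi_a: float, phi_b: float
                ) -> tuple[int, int]:
    """Stratum and column containing (phi_a, phi_b); half-open [lo, hi) cells."""
    i = int(np.searchsorted(part.strata, phi_a, side="right")) - 1
    i = min(max(i, 0), part.n - 1)
    j = int(np.searchsorted(part.columns[i], phi_b, side="right")) - 1
    j = min(max(j, 0), part.n - 1)
    return i, j


def cell_edges(part: EquiprobablePartition, stratum: int, column: int,
               state: int) -> tuple[float, float, float]:
    """Edge lengths (L1, L2, L3) in degrees of one parallelepiped."""
    n = part.n
    if not (0 <= stratum < n and 0 <= column < n and 0 <= state < n):
        raise IndexError("cell index out of range")
    l1 = part.strata[stratum + 1] - part.strata[stratum]
    l2 = part.columns[stratum, column + 1] - part.columns[stratum, column]
    l3 = part.states[stratum, column, state + 1] - part.states[stratum, column, state]
    return float(l1), float(l2), float(l3)


def cell_bounds(part: EquiprobablePartition, stratum: int, column: int,
                state: int) -> tuple[tuple[float, float], ...]:
    """((a1,b1),(a2,b2),(a3,b3)) bounds of one cell in degrees."""
    return ((float(part.strata[stratum]), float(part.strata[stratum + 1])),
            (float(part.columns[stratum, column]),
             float(part.columns[stratum, column + 1])),
            (float(part.states[stratum, column, state]),
             float(part.states[stratum, column, state + 1])))


def cell_integral(grid: EnergyGrid, temperature: float, bounds) -> float:
    """Scaled Boltzmann integral of the trilinear density over a box.

    Uses the tensor-product hat-function expansion, which is exact for the
    piecewise-trilinear density; serves as the equiprobability checker.
    """
    U = grid.values.astype(np.float64)
    s = grid.step
    umin = float(U.min())
    rho = _wrap(_wrap(_wrap(np.exp(-(U - umin) / (KB_KJMOL * temperature)), 0), 1), 2)
    ws = [_hat_weights(grid.n_points, s, a, b) for (a, b) in bounds]
    return float(np.einsum("ijk,i,j,k->", rho, ws[0], ws[1], ws[2]))


def all_cell_integrals(grid: EnergyGrid, temperature: float,
                       part: EquiprobablePartition) -> np.ndarray:
    """(n, n, n) scaled Boltzmann integrals of every cell (exact, vectorized).

    Same hat-function expansion as :func:`cell_integral`; intended for
    verifying the equiprobability contract at moderate n.
    """
    U = grid.values.astype(np.float64)
    s = grid.step
    G = grid.n_points
    n = part.n
    rho = _wrap(_wrap(_wrap(np.exp(-(U - U.min()) / (KB_KJMOL * temperature)), 0),
                      1), 2)
    wx = np.array([_hat_weights(G, s, part.strata[i], part.strata[i + 1])
                   for i in range(n)])                          # (n, G+1)
    t1 = np.einsum("xyz,ix->iyz", rho, wx)
    out = np.empty((n, n, n))
    for i in range(n):
        wy = np.array([_hat_weights(G, s, part.columns[i, j], part.columns[i, j + 1])
                       for j in range(n)])
        t2 = np.einsum("yz,jy->jz", t1[i], wy)                  # (n, G+1)
        for j in range(n):
            wz = np.array([_hat_weights(G, s, part.states[i, j, k],
                                        part.states[i, j, k + 1])
                           for k in range(n)])
            out[i, j] = wz @ t2[j]
    return out


def _hat_weights(G: int, s: float, a: float, b: float) -> np.ndarray:
    """Integrals of the G+1 nodal hat functions over [a, b] (0..360 domain)."""
    w = np.zeros(G + 1)
    i0 = min(int(a // s), G - 1)
    i1 = min(int(b // s), G - 1)
    for i in range(i0, i1 + 1):
        lo = max(a, i * s)
        hi = min(b, (i + 1) * s)
        if hi <= lo:
            continue
        # on segment i: left hat = 1 - (x - i s)/s, right hat = (x - i s)/s
        x0, x1 = lo - i * s, hi - i * s
        right = (x1 * x1 - x0 * x0) / (2.0 * s)
        w[i] += (x1 - x0) - right
        w[i + 1] += right
    return w
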