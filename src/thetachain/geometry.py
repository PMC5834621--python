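"""Torsion vectors to Cartesian coordinates and geometric observables.

Coordinates are built by sequential natural-extension (z-matrix) placement
from the methyl carbon C1, with all bonds and angles at their force-field
equilibrium values.  The dihedral sign convention is right-handed with
0 deg = eclipsed (cis), so trans = 180 deg; the same convention is used for
the torsion grids and the energy maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .topology import ChainTopology


def dihedral_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, 0 = cis, range (-180, 180].

    Accepts arrays shaped (..., 3); broadcasts over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, b2n) * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(p1, p2, p3, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place X given frame atoms so that |X-p1| = bond, ang(X,p1,p2) = angle
    and dih(X,p1,p2,p3) = dihedral (radians).  Broadcasts over (..., 3)."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    b2 = p1 - p2
    b1 = p2 - p3
    u2 = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    n = np.cross(b1, b2)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, u2)
    ca, sa = np.cos(angle), np.sin(angle)
    cd, sd = np.cos(dihedral), np.sin(dihedral)
    d = -u2 * np.asarray(ca)[..., None] + (
        m * np.asarray(cd)[..., None] - n * np.asarray(sd)[..., None]
    ) * np.asarray(sa)[..., None]
    return p1 + bond * d


@dataclass
class CartesianChain:
    topology: ChainTopology
    coords: np.ndarray        # (natoms, 3) nm
    torsions: np.ndarray      # (N-1,) degrees, the inputs used to build

    def backbone_coords(self) -> np.ndarray:
        return self.coords[self.topology.backbone]


def build_cartesian(topo: ChainTopology, torsions) -> CartesianChain:
    """Cartesian coordinates at the given full torsion vector (degrees).

    ``torsions`` may be (N-1,) or a batch (B, N-1); for a batch the returned
    coords have shape (B, natoms, 3).
    """
    phi = np.asarray(torsions, float)
    single = phi.ndim == 1
    phi2 = phi[None, :] if single else phi
    coords = build_cartesian_batch(topo, phi2)
    if single:
        return CartesianChain(topo, coords[0], phi)
    return CartesianChain(topo, coords, phi)


def build_cartesian_batch(topo: ChainTopology, phi_deg: np.ndarray) -> np.ndarray:
    """(B, natoms, 3) coordinates for a batch of full torsion vectors."""
    B = phi_deg.shape[0]
    if phi_deg.shape[1] != topo.N - 1:
        raise ValueError(f"expected {topo.N - 1} torsions")
    phi = np.radians(phi_deg)
    na = topo.natoms
    X = np.zeros((B, na, 3))
    # first three atoms define the frame
    X[:, 0] = 0.0
    X[:, 1, 0] = topo.z_bond[1]
    a2 = topo.z_angle[2]
    X[:, 2, 0] = topo.z_bond[1] - topo.z_bond[2] * math.cos(a2)
    X[:, 2, 1] = topo.z_bond[2] * math.sin(a2)
    for i in range(3, na):
        t = topo.z_tor[i]
        dih = topo.z_off[i] if t < 0 else phi[:, t] + topo.z_off[i]
        X[:, i] = place_atom(X[:, topo.z_p1[i]], X[:, topo.z_p2[i]],
                             X[:, topo.z_p3[i]], topo.z_bond[i],
                             topo.z_angle[i], dih)
    return X


def measure_torsions(chain: CartesianChain) -> np.ndarray:
    """Recompute all N-1 torsions (degrees in [0, 360)) from coordinates."""
    topo = chain.topology
    X = chain.coords
    out = np.empty(topo.N - 1)
    for i, t in enumerate(topo.torsions):
        a, b, c, d = t.quad
        out[i] = dihedral_deg(X[..., a, :], X[..., b, :], X[..., c, :], X[..., d, :]) % 360.0
    return out


def end_to_end_distance(chain: CartesianChain) -> float | np.ndarray:
    """Euclidean distance between the terminal backbone carbons C1 and CN (nm)."""
    X = chain.coords
    i, j = chain.topology.backbone[0], chain.topology.backbone[-1]
    d = np.linalg.norm(X[..., j, :] - X[..., i, :], axis=-1)
    return float(d) if d.ndim == 0 else d


def all_trans_reference(topo: ChainTopology) -> float:
    """End-to-end distance of the fully extended chain (all torsions trans).

    For an unsaturated chain 'all-trans' is ill-defined: the fixed cis
    torsions stay at 0 deg and the value is only an 'extended with cis
    kinks' reference, flagged with a warning.
    """
    if topo.spec.d > 0:
        import warnings
        warnings.warn(f"{topo.spec.name}: all-trans reference computed with "
                      "cis torsions fixed at 0 deg", stacklevel=2)
    phi = topo.torsion_vector(np.full(topo.n_variable, 180.0))
    return end_to_end_distance(build_cartesian(topo, phi))


def zigzag_closed_form(N: int, b0: float, theta0_deg: float) -> float:
    """(N-1) * b0 * sin(theta0/2): planar all-trans end-to-end distance."""
    return (N - 1) * b0 * math.sin(math.radians(theta0_deg) / 2.0)


# ---------------------------------------------------------------------------
# conformer export
# ---------------------------------------------------------------------------

def write_xyz(chain: CartesianChain, fh, comment: str = "") -> None:
    """XYZ in Angstrom; the comment line can carry weight/energy metadata."""
    X = chain.coords * 10.0
    fh.write(f"{chain.topology.natoms}\n{comment}\n")
    for a, r in zip(chain.topology.atoms, X):
        fh.write(f"{a.element} {r[0]:.6f} {r[1]:.6f} {r[2]:.6f}\n")


def write_pdb(chain: CartesianChain, fh) -> None:
    """Minimal single-residue HETATM record set (Angstrom)."""
    X = chain.coords * 10.0
    for a, r in zip(chain.topology.atoms, X):
        name = f"{a.element}{a.index}"[:4]
        fh.write(f"HETATM{a.index + 1:5d} {name:<4s} CHN A   1    "
                 f"{r[0]:8.3f}{r[1]:8.3f}{r[2]:8.3f}  1.00  0.00          "
                 f"{a.element:>2s}\n")
    fh.write("END\n")
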