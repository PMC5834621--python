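"""Compiled inner loops for conformation generation and exact energies.

The kernel consumes pre-generated uniform variates (fixed count per
conformation) so that the scalar numpy reference path and the compiled path
produce identical streams for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _place(x, p1, p2, p3, bond, ca, sa, dih):
    # natural-extension placement; dihedral sign matches geometry.place_atom
    b2x = x[p1, 0] - x[p2, 0]
    b2y = x[p1, 1] - x[p2, 1]
    b2z = x[p1, 2] - x[p2, 2]
    b1x = x[p2, 0] - x[p3, 0]
    b1y = x[p2, 1] - x[p3, 1]
    b1z = x[p2, 2] - x[p3, 2]
    nb2 = (b2x * b2x + b2y * b2y + b2z * b2z) ** 0.5
    u2x, u2y, u2z = b2x / nb2, b2y / nb2, b2z / nb2
    nx = b1y * b2z - b1z * b2y
    ny = b1z * b2x - b1x * b2z
    nz = b1x * b2y - b1y * b2x
    nn = (nx * nx + ny * ny + nz * nz) ** 0.5
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * u2z - nz * u2y
    my = nz * u2x - nx * u2z
    mz = nx * u2y - ny * u2x
    cd = np.cos(dih)
    sd = np.sin(dih)
    dx = -u2x * ca + (mx * cd - nx * sd) * sa
    dy = -u2y * ca + (my * cd - ny * sd) * sa
    dz = -u2z * ca + (mz * cd - nz * sd) * sa
    return x[p1, 0] + bond * dx, x[p1, 1] + bond * dy, x[p1, 2] + bond * dz


@njit(cache=True, fastmath=False)
def sample_measure(uniforms, n, unit_tor, strata, columns, states,
                   phi_template, zp1, zp2, zp3, zbond, zca, zsa, ztor, zoff,
                   pi, pj, pa, pb, pq, ft, fn, fa, fb, econst,
                   first_c, last_c, energy_cap):
    """Generate one batch of conformations; return (h, U, logW, phi).

    uniforms: (B, 6 + 2*(nu-1)) in [0,1).  Unit 0 draws stratum, column and
    state uniformly and the three torsions uniformly inside the cell; every
    later unit inherits its first two torsions, locates the (stratum,
    column), draws a state and the third torsion.  logW accumulates the log
    of the Eq.-style edge-length product.
    """
    B = uniforms.shape[0]
    nu = unit_tor.shape[0]
    ntor = phi_template.shape[0]
    na = zp1.shape[0]
    h = np.empty(B)
    uu = np.empty(B)
    logw = np.empty(B)
    phi_out = np.empty((B, ntor))
    x = np.empty((na, 3))
    for b in range(B):
        phi = phi_template.copy()
        r = uniforms[b]
        # unit 0
        i = min(int(r[0] * n), n - 1)
        j = min(int(r[1] * n), n - 1)
        k = min(int(r[2] * n), n - 1)
        l1 = strata[0, i + 1] - strata[0, i]
        l2 = columns[0, i, j + 1] - columns[0, i, j]
        l3 = states[0, i, j, k + 1] - states[0, i, j, k]
        t1, t2, t3 = unit_tor[0, 0], unit_tor[0, 1], unit_tor[0, 2]
        phi[t1] = strata[0, i] + r[3] * l1
        phi[t2] = columns[0, i, j] + r[4] * l2
        phi[t3] = states[0, i, j, k] + r[5] * l3
        lw = np.log(l1) + np.log(l2) + np.log(l3)
        pos = 6
        for g in range(1, nu):
            ta, tb, tc = unit_tor[g, 0], unit_tor[g, 1], unit_tor[g, 2]
            va = phi[ta]
            vb = phi[tb]
            i = np.searchsorted(strata[g], va, side='right') - 1
            if i < 0:
                i = 0
            elif i > n - 1:
                i = n - 1
            j = np.searchsorted(columns[g, i], vb, side='right') - 1
            if j < 0:
                j = 0
            elif j > n - 1:
                j = n - 1
            k = min(int(r[pos] * n), n - 1)
            l3 = states[g, i, j, k + 1] - states[g, i, j, k]
            phi[tc] = states[g, i, j, k] + r[pos + 1] * l3
            lw += np.log(l3)
            pos += 2
        # cartesian build
        x[0, 0] = 0.0
        x[0, 1] = 0.0
        x[0, 2] = 0.0
        x[1, 0] = zbond[1]
        x[1, 1] = 0.0
        x[1, 2] = 0.0
        x[2, 0] = zbond[1] - zbond[2] * zca[2]
        x[2, 1] = zbond[2] * zsa[2]
        x[2, 2] = 0.0
        phir = phi * (np.pi / 180.0)
        for a in range(3, na):
            t = ztor[a]
            dih = zoff[a] if t < 0 else phir[t] + zoff[a]
            px, py, pz = _place(x, zp1[a], zp2[a], zp3[a], zbond[a],
                                zca[a], zsa[a], dih)
            x[a, 0] = px
            x[a, 1] = py
            x[a, 2] = pz
        # energy
        e = econst
        for m in range(pi.shape[0]):
            ddx = x[pi[m], 0] - x[pj[m], 0]
            ddy = x[pi[m], 1] - x[pj[m], 1]
            ddz = x[pi[m], 2] - x[pj[m], 2]
            r2 = ddx * ddx + ddy * ddy + ddz * ddz
            inv = 1.0 / r2
            r6 = inv * inv * inv
            e += pa[m] * r6 * r6 - pb[m] * r6 + pq[m] * np.sqrt(inv)
        for m in range(ft.shape[0]):
            ang = fn[m] * phir[ft[m]]
            e += fa[m] * np.cos(ang) + fb[m] * np.sin(ang)
        if not np.isfinite(e) or e > energy_cap:
            e = energy_cap
        hx = x[last_c, 0] - x[first_c, 0]
        hy = x[last_c, 1] - x[first_c, 1]
        hz = x[last_c, 2] - x[first_c, 2]
        h[b] = (hx * hx + hy * hy + hz * hz) ** 0.5
        uu[b] = e
        logw[b] = lw
        phi_out[b] = phi
    return h, uu, logw, phi_out
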