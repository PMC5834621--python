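import numpy as np
import pytest

from thetachain.constants import KB_KJMOL
from thetachain.energy import EnergyGrid
from thetachain.partition import (PartitionError, all_cell_integrals,
                                  build_equiprobable_partition, cell_bounds,
                                  cell_edges, cell_integral, locate_cell)

T = 303.0


def make_grid(U, step=3.6):
    return EnergyGrid(unit_key="test", unit_type="toy", step=step,
                      values=np.asarray(U, np.float32))


@pytest.fixture(scope="module")
def double_well_grid():
    G, step = 100, 3.6
    a = np.radians(np.arange(G) * step)
    U = (4.0 * (1 + np.cos(3 * a))[:, None, None]
         + 3.5 * (1 + np.cos(2 * a - 1.0))[None, :, None]
         + 2.0 * (1 + np.cos(a))[None, None, :]
         + 1.5 * np.cos(a[:, None, None] + 2 * a[None, :, None] - a[None, None, :]))
    return make_grid(U)


def test_uniform_grid_gives_equal_spacing():
    g = make_grid(np.zeros((100, 100, 100)))
    p = build_equiprobable_partition(g, T, 100)
    assert np.allclose(np.diff(p.strata), 3.6, atol=1e-12)
    assert np.allclose(np.diff(p.columns, axis=-1), 3.6, atol=1e-12)
    assert np.allclose(np.diff(p.states, axis=-1), 3.6, atol=1e-12)
    assert cell_edges(p, 3, 5, 7) == pytest.approx((3.6, 3.6, 3.6))


def test_separable_grid_matches_1d_inverse_cdf():
    """Energy varying only along the first axis: columns and states stay
    uniform and the strata equal an independently computed 1D inverse CDF."""
    G, step = 100, 3.6
    a = np.radians(np.arange(G) * step)
    u1 = 6.0 * (1 + np.cos(a + 0.7))
    g = make_grid(np.broadcast_to(u1[:, None, None], (G, G, G)).copy())
    n = 40
    p = build_equiprobable_partition(g, T, n)
    assert np.allclose(np.diff(p.columns, axis=-1), 360.0 / n, atol=1e-9)
    assert np.allclose(np.diff(p.states, axis=-1), 360.0 / n, atol=1e-9)
    # independent fine-grid quadrature of the 1D marginal (midpoint rule on
    # a linearly interpolated density)
    fine = np.linspace(0, 360, 720001)
    dens = np.interp(fine, np.arange(G + 1) * step, np.exp(
        -np.append(u1, u1[0]) / (KB_KJMOL * T)))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2
                                           * np.diff(fine))])
    cdf /= cdf[-1]
    expect = np.interp(np.arange(n + 1) / n, cdf, fine)
    assert np.max(np.abs(p.strata - expect)) < 0.05


@pytest.mark.parametrize("n", [20, 50])
def test_equiprobability_every_cell(double_well_grid, n):
    p = build_equiprobable_partition(double_well_grid, T, n)
    target = p.cell_probability_target()
    cells = all_cell_integrals(double_well_grid, T, p)
    assert np.max(np.abs(cells - target)) / target < 1e-3


def test_single_cell_integral_matches_batch(double_well_grid):
    p = build_equiprobable_partition(double_well_grid, T, 20)
    cells = all_cell_integrals(double_well_grid, T, p)
    v = cell_integral(double_well_grid, T, cell_bounds(p, 3, 7, 11))
    assert v == pytest.approx(cells[3, 7, 11], rel=1e-12)


def test_column_states_span_the_axis(double_well_grid):
    p = build_equiprobable_partition(double_well_grid, T, 25)
    l3_sums = p.states[:, :, -1] - p.states[:, :, 0]
    assert np.allclose(l3_sums, 360.0, atol=1e-9)
    assert np.all(np.diff(p.states, axis=-1) > 0)


def test_boundaries_crowd_in_low_energy_regions(double_well_grid):
    """Mean cell volume in the lowest-energy decile of cells is smaller than
    in the highest-energy decile."""
    n = 20
    p = build_equiprobable_partition(double_well_grid, T, n)
    vols = np.empty((n, n, n))
    es = np.empty((n, n, n))
    U = double_well_grid.values.astype(float)
    step = double_well_grid.step
    for i in range(n):
        for j in range(n):
            for k in range(n):
                l1, l2, l3 = cell_edges(p, i, j, k)
                vols[i, j, k] = l1 * l2 * l3
                (a, b), (c, d), (e, f) = cell_bounds(p, i, j, k)
                ic = int(((a + b) / 2) // step) % 100
                jc = int(((c + d) / 2) // step) % 100
                kc = int(((e + f) / 2) // step) % 100
                es[i, j, k] = U[ic, jc, kc]
    lo = es <= np.quantile(es, 0.1)
    hi = es >= np.quantile(es, 0.9)
    assert vols[lo].mean() < vols[hi].mean()
    # smallest cells sit at high density
    assert es.flat[np.argmin(vols)] < np.median(es)


def test_locate_cell_brute_force_and_boundary_convention(double_well_grid):
    p = build_equiprobable_partition(double_well_grid, T, 20)
    rng = np.random.default_rng(0)
    for _ in range(200):
        x, y = rng.uniform(0, 360, 2)
        i, j = locate_cell(p, x, y)
        bi = int(np.sum(p.strata <= x)) - 1
        bi = min(max(bi, 0), 19)
        assert i == bi
        assert p.columns[i, j] <= y and (j == 19 or y < p.columns[i, j + 1])
    # a boundary value belongs to the upper (right) cell: half-open [lo, hi)
    g = make_grid(np.zeros((100, 100, 100)))
    pu = build_equiprobable_partition(g, T, 100)
    assert locate_cell(pu, 0.0, 0.0) == (0, 0)
    assert locate_cell(pu, 3.6, 7.2)[0] == 1
    assert locate_cell(pu, 3.6, 7.2)[1] == 2


def test_determinism(double_well_grid):
    p1 = build_equiprobable_partition(double_well_grid, T, 20)
    p2 = build_equiprobable_partition(double_well_grid, T, 20)
    assert np.array_equal(p1.strata, p2.strata)
    assert np.array_equal(p1.columns, p2.columns)
    assert np.array_equal(p1.states, p2.states)


def test_additive_energy_shift_leaves_boundaries_unchanged(double_well_grid):
    base = EnergyGrid(unit_key="t", unit_type="toy", step=3.6,
                      values=double_well_grid.values.astype(np.float64))
    shifted = EnergyGrid(unit_key="t", unit_type="toy", step=3.6,
                         values=base.values + 25.0)
    p1 = build_equiprobable_partition(base, T, 20)
    p2 = build_equiprobable_partition(shifted, T, 20)
    assert np.array_equal(p1.states, p2.states)


def test_invalid_inputs(double_well_grid):
    with pytest.raises(PartitionError):
        build_equiprobable_partition(double_well_grid, -1.0, 10)
    bad = make_grid(np.zeros((10, 10, 10)), step=36.0)
    bad.values[0, 0, 0] = np.inf
    with pytest.raises(PartitionError):
        build_equiprobable_partition(bad, T, 5)
    p = build_equiprobable_partition(double_well_grid, T, 10)
    with pytest.raises(IndexError):
        cell_edges(p, 10, 0, 0)
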