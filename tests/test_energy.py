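import math

import numpy as np
import pytest
import yaml

import thetachain as tc
from thetachain.constants import KB_KJMOL
from thetachain.energy import (ChainEnergyModel, EnergyGridError,
                               boltzmann_integral, classify_term_multiplier,
                               slice_energy_map)
from thetachain.forcefield import load_parameters, with_zeroed_terms, write_parameters
from thetachain.geometry import build_cartesian_batch, dihedral_deg
from thetachain.topology import build_topology


def brute_force_unit_energy(model, gamma, triple_values, step_base=180.0):
    """Independent oracle: build full Cartesian geometry at the triple and
    sum the unit's owned terms directly (no rotation composition)."""
    topo = model.topology
    u = topo.units[gamma]
    var = np.full(topo.n_variable, step_base)
    for t, v in zip(u.torsion_indices, triple_values):
        var[topo.variable.index(t)] = v
    phi = topo.torsion_vector(var)
    X = build_cartesian_batch(topo, phi[None, :])[0]
    pairs, dihs = model.unit_owned_terms(gamma)
    e = 0.0
    for p, mult in pairs:
        r2 = float(np.sum((X[p.i] - X[p.j]) ** 2))
        inv = 1.0 / r2
        r6 = inv ** 3
        e += mult * (p.a_lj * r6 * r6 - p.b_lj * r6 + p.qq * math.sqrt(inv))
    for d, mult in dihs:
        a, b, c, dd = d.quad
        chi = float(dihedral_deg(X[a], X[b], X[c], X[dd]))
        for t in d.terms:
            e += mult * t.K * (1 + math.cos(math.radians(t.n * chi - t.phase)))
    return e


@pytest.fixture(scope="module")
def toy_model(toy_ff):
    return ChainEnergyModel(build_topology("8:0", toy_ff), toy_ff)


def test_zeroed_forcefield_gives_zero(toy_ff):
    zff = with_zeroed_terms(toy_ff)
    topo = build_topology("8:0", zff)
    m = ChainEnergyModel(topo, zff)
    rng = np.random.default_rng(0)
    phi = topo.torsion_vector(rng.uniform(0, 360, (5, topo.n_variable)))
    assert np.allclose(m.exact_energy_batch(phi), 0.0, atol=1e-12)
    grid = m.tabulate_unit_energy(2, step=24.0, dtype=np.float64)
    assert np.all(grid.values == 0.0)
    sl = slice_energy_map(grid, 3, 48.0)
    assert np.all(sl == 0.0)


def test_single_dihedral_series_closed_form(toy_ff, tmp_path):
    """With only one cosine series on C-C-C-C quads, the interior unit grid
    is (1/3) K (1 + cos 3 phi) summed over its three torsions."""
    p = tmp_path / "dihonly.yaml"
    write_parameters(with_zeroed_terms(toy_ff), p)
    doc = yaml.safe_load(p.read_text())
    # exact key beats the zeroed wildcards retained for lookup coverage
    doc["dihedrals"].append({"types": ["CT2", "CT2", "CT2", "CT2"],
                             "terms": [{"K": 1.0, "n": 3, "phase": 0.0}]})
    p.write_text(yaml.safe_dump(doc))
    ff = load_parameters(p, "native-config")
    topo = build_topology("8:0", ff)
    m = ChainEnergyModel(topo, ff)
    grid = m.tabulate_unit_energy(2, step=12.0, dtype=np.float64)
    ang = np.radians(grid.angles)
    expect = ((1 + np.cos(3 * ang))[:, None, None]
              + (1 + np.cos(3 * ang))[None, :, None]
              + (1 + np.cos(3 * ang))[None, None, :]) / 3.0
    assert np.allclose(grid.values, expect, atol=1e-12)
    assert grid.value_at(180.0, 180.0, 180.0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("chain", ["8:0", "10:2(n-3)cis"])
def test_grid_matches_brute_force_evaluation(toy_ff, chain):
    """Tabulated grids equal direct Cartesian evaluation of the owned terms."""
    topo = build_topology(chain, toy_ff)
    m = ChainEnergyModel(topo, toy_ff)
    rng = np.random.default_rng(1)
    step = 24.0
    for gamma in range(topo.n_f):
        grid = m.tabulate_unit_energy(gamma, step=step, dtype=np.float64)
        for _ in range(8 if gamma % 2 == 0 else 4):
            idx = rng.integers(0, grid.n_points, 3)
            vals = idx * step
            direct = brute_force_unit_energy(m, gamma, vals)
            tab = float(grid.values[idx[0], idx[1], idx[2]])
            assert tab == pytest.approx(direct, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize("chain", ["8:0", "10:2(n-3)cis"])
def test_grid_sum_reproduces_exact_energy(toy_ff, chain):
    """Sum of unit grids = exact variable-term energy: every shared term is
    counted exactly once by the multiplier bookkeeping."""
    topo = build_topology(chain, toy_ff)
    m = ChainEnergyModel(topo, toy_ff)
    step = 24.0
    grids = [m.tabulate_unit_energy(g, step, dtype=np.float64)
             for g in range(topo.n_f)]
    rng = np.random.default_rng(2)
    for _ in range(12):
        idx = rng.integers(0, grids[0].n_points, topo.n_variable)
        var = idx * step
        phi = topo.torsion_vector(var)
        exact_var = m.exact_energy(phi) - m.constant_energy
        gsum = sum(float(g.value_at(*[phi[t] for t in topo.units[i].torsion_indices]))
                   for i, g in enumerate(grids))
        assert gsum == pytest.approx(exact_var, rel=1e-9, abs=1e-7)


def test_exact_energy_independent_oracle(toy_ff):
    """Exact evaluator vs a from-scratch term enumeration on random confs."""
    topo = build_topology("8:0", toy_ff)
    m = ChainEnergyModel(topo, toy_ff)
    rng = np.random.default_rng(3)
    for _ in range(20):
        phi = topo.torsion_vector(rng.uniform(0, 360, topo.n_variable))
        X = build_cartesian_batch(topo, phi[None, :])[0]
        e = m.constant_energy
        for p in m.pairs:
            r = float(np.linalg.norm(X[p.i] - X[p.j]))
            e += p.a_lj / r ** 12 - p.b_lj / r ** 6 + p.qq / r
        for d in m.dihedrals:
            a, b, c, dd = d.quad
            chi = float(dihedral_deg(X[a], X[b], X[c], X[dd]))
            for t in d.terms:
                e += t.K * (1 + math.cos(math.radians(t.n * chi - t.phase)))
        assert m.exact_energy(phi) == pytest.approx(e, rel=1e-9, abs=1e-9)


def test_multiplier_classification(toy_model):
    topo = toy_model.topology
    unit = topo.units[2]          # interior unit, torsions (2, 3, 4)
    assert classify_term_multiplier({3}, unit) == pytest.approx(1 / 3)
    assert classify_term_multiplier({2, 3}, unit) == pytest.approx(1 / 2)
    assert classify_term_multiplier({2, 3, 4}, unit) == pytest.approx(1.0)
    assert classify_term_multiplier(set(), unit) == "constant"
    with pytest.raises(ValueError):
        classify_term_multiplier({1, 2}, unit)


def test_interior_multipliers_match_ownership_counts(toy_model):
    """For interior units the 1/(owner count) rule IS the 1/3-1/2-1 rule."""
    unit = toy_model.topology.units[2]
    pairs, dihs = toy_model.unit_owned_terms(2)
    for p, mult in pairs:
        assert mult == pytest.approx(classify_term_multiplier(p.dependence, unit))
    for d, mult in dihs:
        assert mult == pytest.approx(classify_term_multiplier(d.dependence, unit))


def test_multipliers_sum_to_one(toy_ff):
    for chain in ("8:0", "10:2(n-3)cis"):
        topo = build_topology(chain, toy_ff)
        m = ChainEnergyModel(topo, toy_ff)
        for p in m.pairs:
            assert sum(1.0 / len(p.owners) for _ in p.owners) == pytest.approx(1.0)
        for d in m.dihedrals:
            assert len(d.owners) >= 1


def test_slice_measured_from_global_minimum(toy_model):
    grid = toy_model.tabulate_unit_energy(2, step=24.0, dtype=np.float64)
    amin = np.unravel_index(np.argmin(grid.values), grid.values.shape)
    sl = slice_energy_map(grid, 1, amin[0] * grid.step)
    assert sl.min() == pytest.approx(0.0, abs=1e-9)
    other = slice_energy_map(grid, 1, ((amin[0] + 5) % grid.n_points) * grid.step)
    assert other.min() >= -1e-9   # never below the global minimum


def test_triplet_interdependence(toy_ff):
    """Slices of an allylic unit at two values of the third torsion differ:
    the three torsions are genuinely coupled."""
    topo = build_topology("10:2(n-3)cis", toy_ff)
    m = ChainEnergyModel(topo, toy_ff)
    grid = m.tabulate_unit_energy(1, step=24.0, dtype=np.float64)
    s60 = slice_energy_map(grid, 3, 72.0)
    s120 = slice_energy_map(grid, 3, 120.0)
    assert np.max(np.abs(s60 - s120)) > 0.0


def test_slice_requires_on_grid_value(toy_model):
    grid = toy_model.tabulate_unit_energy(0, step=24.0)
    with pytest.raises(EnergyGridError):
        slice_energy_map(grid, 3, 13.0)
    with pytest.raises(EnergyGridError):
        slice_energy_map(grid, 0, 24.0)


def test_grid_periodicity_and_refinement(toy_model):
    coarse = toy_model.tabulate_unit_energy(2, step=24.0, dtype=np.float64)
    fine = toy_model.tabulate_unit_energy(2, step=12.0, dtype=np.float64)
    # shared nodes coincide
    assert np.allclose(coarse.values, fine.values[::2, ::2, ::2], atol=1e-9)
    zc = boltzmann_integral(coarse, 303.0)
    zf = boltzmann_integral(fine, 303.0)
    assert abs(zc - zf) / zf < 5e-3


def test_additive_shift_cancels_in_boltzmann_ratio(toy_model):
    g = toy_model.tabulate_unit_energy(1, step=24.0, dtype=np.float64)
    shifted = type(g)(unit_key=g.unit_key, unit_type=g.unit_type, step=g.step,
                      values=g.values + 37.0)
    r = boltzmann_integral(shifted, 303.0) / boltzmann_integral(g, 303.0)
    assert r == pytest.approx(math.exp(-37.0 / (KB_KJMOL * 303.0)), rel=1e-9)
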