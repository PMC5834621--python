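import numpy as np
import pytest

import thetachain as tc
from thetachain.energy import ChainEnergyModel
from thetachain.forcefield import with_zeroed_terms
from thetachain.geometry import build_cartesian_batch
from thetachain.oracles import toy_system
from thetachain.sampler import (PartitionSet, SimulationConfig, sample_chain,
                                exact_short_range_energy, run_estimation,
                                uniforms_per_conformation,
                                _torsions_from_uniforms, _kernel_args)
from thetachain.topology import build_topology

from conftest import make_config


@pytest.fixture(scope="module")
def zero_model(toy_ff):
    zff = with_zeroed_terms(toy_ff)
    topo = build_topology("8:0", zff)
    return ChainEnergyModel(topo, zff)


@pytest.fixture(scope="module")
def zero_parts(zero_model):
    return PartitionSet(zero_model, temperature=303.0, grid_step=12.0, n=25)


def test_flat_density_uniform_marginals_and_constant_weights(zero_model, zero_parts):
    """Zero energy: every torsion marginal is uniform and W is constant."""
    from scipy.stats import kstest
    topo = zero_model.topology
    rng = np.random.default_rng(0)
    uni = rng.random((100_000, uniforms_per_conformation(topo)))
    phi, logw, _ = _torsions_from_uniforms(topo, zero_parts, uni)
    assert np.allclose(logw, logw[0], atol=1e-12)   # constant weights
    n_edges = 3 + (topo.n_f - 1)
    assert logw[0] == pytest.approx(n_edges * np.log(360.0 / zero_parts.n))
    for t in topo.variable:
        p = kstest(phi[:, t] / 360.0, "uniform").pvalue
        assert p > 0.01, f"torsion {t} marginal not uniform (p={p:.2g})"


def test_weight_factor_count(zero_model, zero_parts):
    """Weight = L1 L2 L3 x one L3 per later unit: N_f + 2 edge factors."""
    topo = zero_model.topology   # saturated N=8 -> N_f = 5
    rng = np.random.default_rng(1)
    conf = sample_chain(topo, zero_parts, rng, zero_model)
    edge = 360.0 / zero_parts.n
    assert topo.n_f == 5
    assert conf.weight == pytest.approx(edge ** (3 + (topo.n_f - 1)), rel=1e-12)
    assert len(conf.cells) == topo.n_f


def test_sample_chain_cells_consistent(model_cache, toy_partitions):
    m = model_cache("8:0")
    topo = m.topology
    rng = np.random.default_rng(2)
    for _ in range(20):
        conf = sample_chain(topo, toy_partitions, rng, m)
        assert np.all((conf.torsions >= 0) & (conf.torsions < 360))
        assert conf.weight > 0
        assert conf.u_units == pytest.approx(
            exact_short_range_energy(conf, topo, m))
        for g, (i, j, k) in enumerate(conf.cells):
            part = toy_partitions.partition_for(g)
            t1, t2, t3 = topo.units[g].torsion_indices
            assert part.strata[i] <= conf.torsions[t1] < part.strata[i + 1]
            assert part.columns[i, j] <= conf.torsions[t2] < part.columns[i, j + 1]
            assert part.states[i, j, k] <= conf.torsions[t3] \
                < part.states[i, j, k + 1]


def test_engines_agree_bitwise_inputs(model_cache, toy_partitions):
    """The compiled kernel and the numpy path consume identical variates and
    must return the same torsions, energies and weights."""
    from thetachain._kernels import sample_measure
    from thetachain.sampler import _measure_numpy
    m = model_cache("8:0")
    rng = np.random.default_rng(3)
    uni = rng.random((500, uniforms_per_conformation(m.topology)))
    h1, e1, lw1, phi1 = _measure_numpy(m, toy_partitions, uni)
    h2, e2, lw2, phi2 = sample_measure(uni, *_kernel_args(m, toy_partitions))
    assert np.allclose(phi1, phi2, atol=1e-12)
    assert np.allclose(h1, h2, atol=1e-12)
    assert np.allclose(e1, e2, atol=1e-9)
    assert np.allclose(lw1, lw2, atol=1e-12)


def test_seed_determinism_and_seed_independence(model_cache, toy_partitions):
    m = model_cache("8:0")
    cfg = make_config(samples=30_000, seed=7)
    r1 = run_estimation(m, toy_partitions, cfg)
    r2 = run_estimation(m, toy_partitions, cfg)
    assert r1["h"].estimate == r2["h"].estimate   # bit-identical
    cfg2 = make_config(samples=30_000, seed=8)
    r3 = run_estimation(m, toy_partitions, cfg2)
    sigma = np.hypot(r1["h"].error, r3["h"].error)
    assert abs(r1["h"].estimate - r3["h"].estimate) < 4 * sigma


def test_batch_schedule_does_not_change_the_stream(model_cache, toy_partitions):
    m = model_cache("8:0")
    a = run_estimation(m, toy_partitions, make_config(samples=10_000, seed=5,
                                                      batch_size=1024))
    b = run_estimation(m, toy_partitions, make_config(samples=10_000, seed=5,
                                                      batch_size=65536))
    assert a["h"].estimate == pytest.approx(b["h"].estimate, rel=1e-12)


def test_joint_density_matches_quadrature(toy_ff):
    """Two-unit system: the weighted sampler reproduces the Boltzmann joint
    law of its four free torsions, checked on a basis of smooth cross
    moments (periodic trapezoid quadrature is spectrally accurate there)."""
    sys4 = toy_system(toy_ff, "8:0", free=(1, 2, 3, 4))
    topo = sys4.topology
    assert topo.n_f == 2
    step = 12.0
    G = int(360 / step)
    axes = [np.arange(G) * step] * 4
    mesh = np.meshgrid(*axes, indexing="ij")
    var = np.stack([m.ravel() for m in mesh], axis=-1)
    from thetachain.constants import KB_KJMOL
    e = np.empty(var.shape[0])
    for lo in range(0, var.shape[0], 65536):
        phi = topo.torsion_vector(var[lo:lo + 65536])
        e[lo:lo + 65536] = sys4.model.exact_energy_batch(phi)
    w = np.exp(-(e - e.min()) / (KB_KJMOL * 303.0))
    t1, t2, t3, t4 = 1, 2, 3, 4   # the free torsion indices

    def moments(phi_deg):
        r = np.radians(phi_deg)
        return np.stack([
            np.cos(r[:, t1]), np.cos(r[:, t2]),
            np.cos(r[:, t1]) * np.cos(r[:, t2]),
            np.sin(r[:, t2]) * np.sin(r[:, t3]),
            np.cos(r[:, t1] + r[:, t2] - r[:, t3]),
            np.cos(r[:, t2]) * np.cos(r[:, t4]),
            np.sin(r[:, t1]) * np.sin(r[:, t4]),
        ], axis=-1)

    mvals = np.empty((var.shape[0], 7))
    for lo in range(0, var.shape[0], 65536):
        mvals[lo:lo + 65536] = moments(topo.torsion_vector(var[lo:lo + 65536]))
    ref = (w[:, None] * mvals).sum(axis=0) / w.sum()

    parts = PartitionSet(sys4.model, 303.0, grid_step=7.2, n=40)
    cfg = SimulationConfig(temperature=303.0, samples=150_000, grid_step=7.2,
                           subdivisions=40, seed=9, blocks=20)
    obs = []
    for c in range(7):
        f = (lambda cc: lambda phi, coords: moments(phi)[:, cc])(c)
        f.__name__ = f"m{c}"
        obs.append(f)
    res = run_estimation(sys4.model, parts, cfg, observables=obs)
    for c in range(7):
        v = res[f"m{c}"]
        sig = max(v.error, v.error_iid, 1e-6)
        assert abs(v.estimate - ref[c]) < 4 * sig, \
            f"moment {c}: {v.estimate:.5f} vs {ref[c]:.5f} (sigma {sig:.2g})"


def test_degenerate_agreement_grid_sum_vs_exact(toy_ff, tmp_path):
    """Force field with only fully-unit-owned (multiplier 1) terms: the
    proposal grid-sum energy equals the exact energy up to the constant."""
    import yaml
    from thetachain.forcefield import load_parameters, write_parameters
    p = tmp_path / "ff.yaml"
    write_parameters(with_zeroed_terms(toy_ff), p)
    doc = yaml.safe_load(p.read_text())
    # one live series on the backbone quads of a 3-free-torsion system: the
    # single unit owns everything with multiplier 1 (zeroed wildcards stay
    # so that every topology lookup still resolves)
    doc["dihedrals"].append({"types": ["CT2", "CT2", "CT2", "CT2"],
                             "terms": [{"K": 2.0, "n": 3, "phase": 0.0}]})
    p.write_text(yaml.safe_dump(doc))
    ff = load_parameters(p, "native-config")
    sys3 = toy_system(ff, "8:0", free=(2, 3, 4))
    m = sys3.model
    assert m.topology.n_f == 1
    grid = m.tabulate_unit_energy(0, step=12.0, dtype=np.float64)
    rng = np.random.default_rng(11)
    for _ in range(10):
        idx = rng.integers(0, grid.n_points, 3)
        var = idx * 12.0
        phi = m.topology.torsion_vector(var)
        assert float(grid.values[tuple(idx)]) == pytest.approx(
            m.exact_energy(phi) - m.constant_energy, abs=1e-9)


def test_constant_observable_is_exact(model_cache, toy_partitions):
    m = model_cache("8:0")
    cfg = make_config(samples=5_000, seed=13)
    const = lambda phi, coords: np.full(phi.shape[0], 2.5)
    const.__name__ = "const"
    res = run_estimation(m, toy_partitions, cfg, observables=(const,))
    assert res["const"].estimate == pytest.approx(2.5, abs=1e-12)
    assert res["const"].error == pytest.approx(0.0, abs=1e-12)


def test_effective_sample_size_bounds(model_cache, toy_partitions):
    m = model_cache("8:0")
    res = run_estimation(m, toy_partitions, make_config(samples=20_000, seed=4))
    v = res["h"]
    assert 1.0 <= v.effective_samples <= v.omega
    assert v.error >= 0 and v.error_iid >= 0


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(temperature=-1)
    with pytest.raises(ValueError):
        SimulationConfig(samples=5, blocks=10)
    with pytest.raises(ValueError):
        SimulationConfig(samples=0)
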