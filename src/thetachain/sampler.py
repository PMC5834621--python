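"""Weighted conformation generation and the self-normalised estimator.

Conformations are generated unit by unit: the first unit draws a stratum,
column and state uniformly (each 1/n) from its equiprobable partition and
the three torsions uniformly inside the chosen cell; every later unit
inherits its first two torsions from the previous one, locates the stratum
and column containing them, draws a state uniformly along the third axis
and the remaining torsion uniformly inside it.  The proposal density is
therefore 1/(n^3 L1 L2 L3) x prod 1/(n L3): the uniform 1/n factors cancel
in the self-normalised average, leaving the edge-length product

    W = L1 L2 L3 (first unit) x prod_(gamma >= 2) L3,

and each observable is estimated as

    Hbar = sum H exp(-U_units/kT) W / sum exp(-U_units/kT) W,

with U_units the exact short-range energy of the generated conformation.
The estimate is consistent for any partition and any grid step: those
choices affect only the variance, never the limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KJMOL
from .energy import ChainEnergyModel
from .geometry import build_cartesian_batch
from .partition import EquiprobablePartition, build_equiprobable_partition, locate_cell
from .topology import ChainTopology

#: conformations flagged non-finite are clamped to this energy (kJ/mol),
#: contributing (numerically) zero Boltzmann weight but never being dropped
ENERGY_CAP = 1.0e6


@dataclass
class SimulationConfig:
    temperature: float = DEFAULT_TEMPERATURE
    samples: int = 100_000
    grid_step: float = 3.6
    subdivisions: int = 100
    seed: int = 0
    blocks: int = 10
    batch_size: int = 65536

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.samples < 1:
            raise ValueError("need at least one sample")
        if not (1 <= self.blocks <= self.samples):
            raise ValueError("blocks must be in [1, samples]")


@dataclass
class Conformation:
    torsions: np.ndarray            # full phi vector, degrees in [0, 360)
    cells: list                     # per unit (stratum, column, state)
    weight: float                   # W, product of chosen edge lengths (deg^k)
    u_units: float                  # exact short-range energy, kJ/mol
    approx_u: float | None = None   # grid-sum energy of the proposal, if requested


@dataclass
class WeightedEstimate:
    observable: str
    estimate: float
    error: float            # block-average statistical error
    error_iid: float        # error from the weighted per-conformation variance
    effective_samples: float
    omega: int
    blocks: int
    flagged: int = 0        # conformations clamped at the energy cap


class PartitionSet:
    """Per-unit partitions of one chain (shared grids deduplicated by key)."""

    def __init__(self, model: ChainEnergyModel, temperature: float,
                 grid_step: float, n: int, grids: dict | None = None):
        self.model = model
        self.temperature = temperature
        self.n = n
        self.grid_step = grid_step
        topo = model.topology
        self.grids = {}
        self.partitions: dict[str, EquiprobablePartition] = {}
        self.unit_keys: list[str] = []
        cache = grids or {}
        for u in topo.units:
            key = model.unit_key(u.gamma)
            self.unit_keys.append(key)
            if key not in self.partitions:
                grid = cache.get(key)
                if grid is None:
                    grid = model.tabulate_unit_energy(u.gamma, grid_step)
                self.grids[key] = grid
                self.partitions[key] = build_equiprobable_partition(
                    grid, temperature, n)

    def partition_for(self, gamma: int) -> EquiprobablePartition:
        return self.partitions[self.unit_keys[gamma]]

    def stacked_arrays(self):
        """(strata, columns, states) stacked per unit for the kernels."""
        n = self.n
        nu = len(self.unit_keys)
        strata = np.empty((nu, n + 1))
        columns = np.empty((nu, n, n + 1))
        states = np.empty((nu, n, n, n + 1))
        for g, key in enumerate(self.unit_keys):
            p = self.partitions[key]
            strata[g] = p.strata
            columns[g] = p.columns
            states[g] = p.states
        return strata, columns, states


def uniforms_per_conformation(topo: ChainTopology) -> int:
    return 6 + 2 * (topo.n_f - 1)


def sample_chain(topo: ChainTopology, partitions: PartitionSet,
                 rng: np.random.Generator,
                 model: ChainEnergyModel | None = None) -> Conformation:
    """Generate one weighted conformation (readable scalar reference path)."""
    u = rng.random(uniforms_per_conformation(topo))
    phi, logw, cells = _torsions_from_uniforms(topo, partitions, u[None, :])
    model = model or partitions.model
    e = float(model.exact_energy_batch(phi)[0])
    return Conformation(torsions=phi[0], cells=cells[0],
                        weight=float(np.exp(logw[0])), u_units=e)


def _torsions_from_uniforms(topo: ChainTopology, parts: PartitionSet,
                            uniforms: np.ndarray):
    """Vectorised torsion generation; same variate order as the kernel."""
    B = uniforms.shape[0]
    n = parts.n
    phi = np.tile(topo.torsion_vector(np.zeros(topo.n_variable)), (B, 1))
    logw = np.zeros(B)
    cells = [[] for _ in range(B)]
    strata, columns, states = parts.stacked_arrays()
    u0 = topo.units[0]
    i = np.minimum((uniforms[:, 0] * n).astype(np.int64), n - 1)
    j = np.minimum((uniforms[:, 1] * n).astype(np.int64), n - 1)
    k = np.minimum((uniforms[:, 2] * n).astype(np.int64), n - 1)
    l1 = strata[0, i + 1] - strata[0, i]
    l2 = columns[0, i, j + 1] - columns[0, i, j]
    l3 = states[0, i, j, k + 1] - states[0, i, j, k]
    t1, t2, t3 = u0.torsion_indices
    phi[:, t1] = strata[0, i] + uniforms[:, 3] * l1
    phi[:, t2] = columns[0, i, j] + uniforms[:, 4] * l2
    phi[:, t3] = states[0, i, j, k] + uniforms[:, 5] * l3
    logw += np.log(l1) + np.log(l2) + np.log(l3)
    for b in range(B):
        cells[b].append((int(i[b]), int(j[b]), int(k[b])))
    pos = 6
    for g in range(1, topo.n_f):
        ta, tb, tc = topo.units[g].torsion_indices
        i = np.clip(np.searchsorted(strata[g], phi[:, ta], side="right") - 1,
                    0, n - 1)
        j = np.clip(
            (columns[g, i] <= phi[:, tb, None]).sum(axis=1) - 1, 0, n - 1)
        k = np.minimum((uniforms[:, pos] * n).astype(np.int64), n - 1)
        l3 = states[g, i, j, k + 1] - states[g, i, j, k]
        phi[:, tc] = states[g, i, j, k] + uniforms[:, pos + 1] * l3
        logw += np.log(l3)
        for b in range(B):
            cells[b].append((int(i[b]), int(j[b]), int(k[b])))
        pos += 2
    return phi, logw, cells


def exact_short_range_energy(conf: Conformation, topo: ChainTopology,
                             model: ChainEnergyModel) -> float:
    """U_units of one conformation (kJ/mol), every owned term counted once."""
    return float(model.exact_energy_batch(conf.torsions[None, :])[0])


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _kernel_args(model: ChainEnergyModel, parts: PartitionSet):
    topo = model.topology
    strata, columns, states = parts.stacked_arrays()
    unit_tor = np.array([u.torsion_indices for u in topo.units], np.int64)
    phi_template = topo.torsion_vector(np.zeros(topo.n_variable))
    zca = np.cos(topo.z_angle)
    zsa = np.sin(topo.z_angle)
    return (parts.n, unit_tor, strata, columns, states, phi_template,
            topo.z_p1, topo.z_p2, topo.z_p3, topo.z_bond, zca, zsa,
            topo.z_tor, np.asarray(topo.z_off, float),
            model.pair_i, model.pair_j, model.pair_a, model.pair_b,
            model.pair_q,
            model.four_t, model.four_n, model.four_a, model.four_b,
            model.dihedral_const + model.constant_energy,
            topo.backbone[0], topo.backbone[-1], ENERGY_CAP)


def _measure_numpy(model, parts, uniforms):
    topo = model.topology
    phi, logw, _ = _torsions_from_uniforms(topo, parts, uniforms)
    coords = build_cartesian_batch(topo, phi)
    e = model.exact_energy_batch(phi, coords=coords)
    e = np.where(np.isfinite(e), np.minimum(e, ENERGY_CAP), ENERGY_CAP)
    i0, i1 = topo.backbone[0], topo.backbone[-1]
    h = np.linalg.norm(coords[:, i1] - coords[:, i0], axis=-1)
    return h, e, logw, phi


def run_estimation(model: ChainEnergyModel, partitions: PartitionSet,
                   config: SimulationConfig, observables=("h",),
                   engine: str = "numba") -> dict[str, WeightedEstimate]:
    """Estimate Boltzmann averages over ``config.samples`` conformations.

    ``observables`` may contain the names ``"h"`` (end-to-end distance, nm)
    and ``"h2"`` (its square), or callables ``f(phi_deg, coords) -> array``;
    callables force the numpy evaluation path for their batch.
    """
    topo = model.topology
    kT = KB_KJMOL * config.temperature
    rng = np.random.default_rng(config.seed)
    nrand = uniforms_per_conformation(topo)
    omega = config.samples
    nblocks = config.blocks
    names = [ob if isinstance(ob, str) else getattr(ob, "__name__", "obs")
             for ob in observables]
    for ob in observables:
        if isinstance(ob, str) and ob not in ("h", "h2"):
            raise ValueError(f"unknown observable name {ob!r}")
    needs_callable = any(callable(ob) for ob in observables)

    if engine == "numba" and not needs_callable:
        from ._kernels import sample_measure
        args = _kernel_args(model, partitions)
    elif engine not in ("numba", "numpy"):
        raise ValueError(f"unknown engine {engine!r}")

    nobs = len(observables)
    num = np.zeros((nblocks, nobs))
    den = np.zeros(nblocks)
    sum_w2 = 0.0
    sum_wh2 = np.zeros(nobs)
    shift = -np.inf
    flagged = 0
    done = 0
    while done < omega:
        B = min(config.batch_size, omega - done)
        uniforms = rng.random((B, nrand))
        if engine == "numba" and not needs_callable:
            h, e, logw_prop, phi = sample_measure(uniforms, *args)
            coords = None
        else:
            h, e, logw_prop, phi = _measure_numpy(model, partitions, uniforms)
            coords = None
        flagged += int(np.sum(e >= ENERGY_CAP))
        logw = -e / kT + logw_prop
        obs_vals = np.empty((B, nobs))
        for c, ob in enumerate(observables):
            if ob == "h":
                obs_vals[:, c] = h
            elif ob == "h2":
                obs_vals[:, c] = h * h
            else:
                if coords is None:
                    coords = build_cartesian_batch(topo, phi)
                obs_vals[:, c] = ob(phi, coords)
        m = float(np.max(logw))
        if m > shift:
            if np.isfinite(shift):
                f = math.exp(shift - m)
                num *= f
                den *= f
                sum_w2 *= f * f
                sum_wh2 *= f
            shift = m
        w = np.exp(logw - shift)
        blocks = ((done + np.arange(B)) * nblocks) // omega
        den += np.bincount(blocks, weights=w, minlength=nblocks)
        for c in range(nobs):
            num[:, c] += np.bincount(blocks, weights=w * obs_vals[:, c],
                                     minlength=nblocks)
        sum_w2 += float(np.sum(w * w))
        sum_wh2 += (w[:, None] * obs_vals ** 2).sum(axis=0)
        done += B

    tot_den = float(den.sum())
    if tot_den <= 0.0:
        raise RuntimeError("all conformations carry zero weight")
    ess = tot_den ** 2 / sum_w2
    out = {}
    for c, name in enumerate(names):
        est = float(num[:, c].sum() / tot_den)
        hb = num[:, c] / np.maximum(den, 1e-300)
        if nblocks > 1:
            berr = float(np.sqrt(np.sum((hb - est) ** 2)
                                 / (nblocks * (nblocks - 1))))
        else:
            berr = float("nan")
        var_w = max(float(sum_wh2[c] / tot_den - est * est), 0.0)
        out[name] = WeightedEstimate(
            observable=name, estimate=est, error=berr,
            error_iid=math.sqrt(var_w / max(ess, 1.0)),
            effective_samples=float(ess), omega=omega, blocks=nblocks,
            flagged=flagged)
    return out


def build_partitions(model: ChainEnergyModel, config: SimulationConfig,
                     grids: dict | None = None) -> PartitionSet:
    """Tabulate (or reuse) grids and build all partitions for one chain."""
    return PartitionSet(model, config.temperature, config.grid_step,
                        config.subdivisions, grids=grids)
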