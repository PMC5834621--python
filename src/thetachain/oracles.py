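"""Reference computations and toy systems for validating the sampler.

The toy systems are real chain topologies in which most torsions are frozen
at trans (180 deg), leaving at most a handful of free torsions, so the full
unit/partition/sampling machinery runs unchanged while the canonical
average remains computable by dense deterministic quadrature.  A
single-torsion-update Metropolis chain provides a second, independent
stochastic route; the three answers must agree.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .constants import KB_KJMOL
from .energy import ChainEnergyModel
from .forcefield import ForceFieldParameters
from .geometry import build_cartesian_batch
from .topology import (ChainTopology, StructuralUnit, TorsionInfo,
                       _pattern, _span_for_triple, build_topology)


class OracleError(ValueError):
    pass


def freeze_torsions(topo: ChainTopology, frozen: dict[int, float]) -> ChainTopology:
    """Copy of a topology with extra torsions pinned (0-based index -> degrees).

    Frozen torsions leave the variable set; structural units are rebuilt
    over the remaining variable torsions.  With fewer than three variable
    torsions the unit list is empty (quadrature and Metropolis still work,
    the stratified sampler does not).
    """
    torsions = []
    for i, t in enumerate(topo.torsions):
        if i in frozen:
            if not t.variable:
                raise OracleError(f"torsion {i} is already fixed")
            torsions.append(dataclasses.replace(t, variable=False,
                                                fixed_value=frozen[i] % 360.0))
        else:
            torsions.append(t)
    variable = [i for i, t in enumerate(torsions) if t.variable]
    units = []
    if len(variable) >= 3:
        spec = topo.spec
        for g in range(len(variable) - 2):
            tri = tuple(variable[g:g + 3])
            lo, hi = _span_for_triple(tri, spec.N)
            span = set(range(lo - 1, hi))
            for a in topo.atoms:
                if a.is_h and lo <= a.pos <= hi:
                    span.add(a.index)
            units.append(StructuralUnit(
                gamma=g, torsion_indices=tri, span_carbons=(lo, hi),
                atom_span=frozenset(span), unit_type=_pattern(spec, (lo, hi))))
    out = ChainTopology(
        spec=topo.spec, atoms=topo.atoms, bonds=topo.bonds,
        backbone=topo.backbone, torsions=torsions, variable=variable,
        units=units, z_p1=topo.z_p1, z_p2=topo.z_p2, z_p3=topo.z_p3,
        z_bond=topo.z_bond, z_angle=topo.z_angle, z_tor=topo.z_tor,
        z_off=topo.z_off)
    out._move_cache = topo._move_cache
    return out


@dataclass
class ToyChainSystem:
    """A small chain with most torsions frozen; quadrature stays cheap."""

    name: str
    topology: ChainTopology
    model: ChainEnergyModel

    @property
    def n_free(self) -> int:
        return self.topology.n_variable


def toy_system(params: ForceFieldParameters, chain: str = "8:0",
               free: tuple[int, ...] = (2, 3, 4)) -> ToyChainSystem:
    """Build a toy system from ``chain`` keeping only ``free`` torsions mobile."""
    topo = build_topology(chain, params)
    frozen = {i: 180.0 for i in range(topo.N - 1)
              if i not in free and topo.torsions[i].variable}
    ftopo = freeze_torsions(topo, frozen)
    return ToyChainSystem(name=f"{chain}/free={free}", topology=ftopo,
                          model=ChainEnergyModel(ftopo, params))


def quadrature_average(system: ToyChainSystem, temperature: float,
                       observable="h", step: float = 3.0,
                       refine_check: bool = False):
    """Dense-grid estimate of the canonical average over the free torsions.

    Returns (value, discretization) where ``discretization`` is the change
    under halving the step (only when ``refine_check``); the trapezoid rule
    on the periodic cube makes the weights a plain Riemann sum.
    """
    nf = system.n_free
    if nf > 3:
        raise OracleError("quadrature limited to systems with <= 3 free torsions")

    def run(st):
        g = 360.0 / st
        if abs(g - round(g)) > 1e-9:
            raise OracleError("step must divide 360")
        G = int(round(g))
        axes = [np.arange(G) * st] * nf
        mesh = np.meshgrid(*axes, indexing="ij")
        var = np.stack([m.ravel() for m in mesh], axis=-1)
        topo = system.topology
        i0, i1 = topo.backbone[0], topo.backbone[-1]
        # streaming accumulation: the grids grow as G^nf
        num = 0.0
        den = 0.0
        eref = None
        for lo in range(0, var.shape[0], 65536):
            chunk = var[lo:lo + 65536]
            phi = topo.torsion_vector(chunk)
            coords = build_cartesian_batch(topo, phi)
            e = system.model.exact_energy_batch(phi, coords=coords)
            if eref is None:
                eref = float(e.min())
            w = np.exp(-(e - eref) / (KB_KJMOL * temperature))
            if observable == "h":
                hvals = np.linalg.norm(coords[:, i1] - coords[:, i0], axis=-1)
            elif observable == "h2":
                hvals = np.sum((coords[:, i1] - coords[:, i0]) ** 2, axis=-1)
            elif callable(observable):
                hvals = observable(phi, coords)
            else:
                raise OracleError(f"unknown observable {observable!r}")
            num += float(np.sum(hvals * w))
            den += float(np.sum(w))
        return num / den

    v = run(step)
    if refine_check:
        return v, abs(v - run(step / 2.0))
    return v, None


def metropolis_reference(system: ToyChainSystem, temperature: float,
                         steps: int, rng: np.random.Generator,
                         walkers: int = 32, burn_in: int | None = None,
                         observable="h"):
    """Single-torsion-update Metropolis sampling of the same Boltzmann law.

    Returns (mean, standard error, acceptance rate); the error combines the
    walker-to-walker spread of post-burn-in means.
    """
    topo = system.topology
    model = system.model
    kT = KB_KJMOL * temperature
    nf = system.n_free
    if burn_in is None:
        burn_in = steps // 5
    var = rng.uniform(0.0, 360.0, (walkers, nf))
    phi = topo.torsion_vector(var)
    e = model.exact_energy_batch(phi)
    i0, i1 = topo.backbone[0], topo.backbone[-1]

    def measure(phi_):
        coords = build_cartesian_batch(topo, phi_)
        if observable == "h":
            return np.linalg.norm(coords[:, i1] - coords[:, i0], axis=-1)
        if observable == "h2":
            return np.sum((coords[:, i1] - coords[:, i0]) ** 2, axis=-1)
        return observable(phi_, coords)

    acc = 0
    tot = 0
    sums = np.zeros(walkers)
    counts = 0
    for step_i in range(steps):
        t_choice = rng.integers(0, nf, walkers)
        prop = var.copy()
        prop[np.arange(walkers), t_choice] = rng.uniform(0, 360.0, walkers)
        phi_p = topo.torsion_vector(prop)
        e_p = model.exact_energy_batch(phi_p)
        accept = rng.random(walkers) < np.exp(np.minimum(-(e_p - e) / kT, 0.0))
        var[accept] = prop[accept]
        e[accept] = e_p[accept]
        acc += int(accept.sum())
        tot += walkers
        if step_i >= burn_in:
            sums += measure(topo.torsion_vector(var))
            counts += 1
    means = sums / counts
    mean = float(means.mean())
    se = float(means.std(ddof=1) / np.sqrt(walkers))
    return mean, se, acc / tot
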