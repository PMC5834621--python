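"""HDF5 persistence for unit-energy grids and equiprobable partitions.

One container holds a ``grids/`` and a ``partitions/`` group; entries are
keyed by the unit content hash (plus temperature and n for partitions), so
editing any force-field constant changes the key and invalidates the cache.
"""

from __future__ import annotations

import numpy as np
import h5py

from .energy import EnergyGrid
from .partition import EquiprobablePartition


def _sanitize(key: str) -> str:
    return key.replace("/", "|")


def save_grid(path, grid: EnergyGrid) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group("grids")
        name = _sanitize(grid.unit_key)
        if name in g:
            del g[name]
        ds = g.create_dataset(name, data=grid.values, compression="gzip",
                              compression_opts=4)
        ds.attrs["step"] = grid.step
        ds.attrs["unit_type"] = grid.unit_type
        ds.attrs["unit_key"] = grid.unit_key
        ds.attrs["convention"] = grid.convention
        ds.attrs["energy_unit"] = "kJ/mol"
        for k, v in grid.provenance.items():
            ds.attrs[f"prov_{k}"] = v


def load_grid(path, unit_key: str) -> EnergyGrid | None:
    with h5py.File(path, "r") as f:
        name = _sanitize(unit_key)
        if "grids" not in f or name not in f["grids"]:
            return None
        ds = f["grids"][name]
        prov = {k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in ds.attrs.items() if k.startswith("prov_")}
        return EnergyGrid(unit_key=ds.attrs["unit_key"],
                          unit_type=ds.attrs["unit_type"],
                          step=float(ds.attrs["step"]),
                          values=ds[()], convention=ds.attrs["convention"],
                          provenance=prov)


def _part_name(unit_key: str, temperature: float, n: int) -> str:
    return _sanitize(f"{unit_key}@T{temperature:g}@n{n}")


def save_partition(path, part: EquiprobablePartition) -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group("partitions")
        name = _part_name(part.unit_key, part.temperature, part.n)
        if name in g:
            del g[name]
        gg = g.create_group(name)
        gg.create_dataset("strata", data=part.strata)
        gg.create_dataset("columns", data=part.columns)
        gg.create_dataset("states", data=part.states, compression="gzip",
                          compression_opts=4)
        gg.attrs.update({"unit_key": part.unit_key, "temperature": part.temperature,
                         "n": part.n, "z_scaled": part.z_scaled,
                         "u_shift": part.u_shift})
        for k, v in part.provenance.items():
            gg.attrs[f"prov_{k}"] = v


def load_partition(path, unit_key: str, temperature: float, n: int
                   ) -> EquiprobablePartition | None:
    with h5py.File(path, "r") as f:
        name = _part_name(unit_key, temperature, n)
        if "partitions" not in f or name not in f["partitions"]:
            return None
        gg = f["partitions"][name]
        prov = {k[5:]: (v.item() if hasattr(v, "item") else v)
                for k, v in gg.attrs.items() if k.startswith("prov_")}
        return EquiprobablePartition(
            unit_key=gg.attrs["unit_key"], temperature=float(gg.attrs["temperature"]),
            n=int(gg.attrs["n"]), strata=gg["strata"][()],
            columns=gg["columns"][()], states=gg["states"][()],
            z_scaled=float(gg.attrs["z_scaled"]), u_shift=float(gg.attrs["u_shift"]),
            provenance=prov)


def export_slice_tsv(path, slice2d: np.ndarray, step: float) -> None:
    """Write a 2D energy map as a TSV matrix with angle headers."""
    G = slice2d.shape[0]
    ang = [f"{i * step:g}" for i in range(G)]
    with open(path, "w") as fh:
        fh.write("deg\t" + "\t".join(ang) + "\n")
        for i in range(G):
            fh.write(ang[i] + "\t" + "\t".join(f"{v:.6g}" for v in slice2d[i]) + "\n")
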