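"""Configuration files, field persistence, run manifests and records.

* configs are flat YAML with keys named exactly as the ``ModelParams``
  fields, plus optional ``grid``, ``seed`` and ``experiment`` blocks;
* fields go to HDF5 (``/cells/<i>/{phi,rho,I}``, ``/pattern/chi``) with
  grid spacing and time as attributes;
* collision records append to JSON-lines files;
* every run can emit a ``RunManifest`` documenting inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .domain import Micropattern, ScalarField
from .engine import CellState, SimulationState
from .params import GridSpec, ModelParams

__all__ = [
    "load_config", "save_config", "save_state", "load_state",
    "RunManifest", "write_records", "read_records",
]

_GRID_KEYS = {f.name for f in dataclasses.fields(GridSpec)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def load_config(path) -> dict:
    """Parse a YAML config into params, grid, seed and experiment plan."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    param_kwargs = {k: v for k, v in raw.items() if k in _PARAM_KEYS}
    grid_kwargs = raw.get("grid", {}) or {}
    unknown = set(grid_kwargs) - _GRID_KEYS
    if unknown:
        raise KeyError(f"unknown grid key(s): {sorted(unknown)}")
    extras = set(raw) - _PARAM_KEYS - {"grid", "seed", "experiment"}
    if extras:
        raise KeyError(f"unknown config key(s): {sorted(extras)}")
    return {
        "params": ModelParams.from_dict(param_kwargs),
        "grid": GridSpec(**grid_kwargs) if grid_kwargs else None,
        "seed": int(raw.get("seed", 0)),
        "experiment": raw.get("experiment", {}) or {},
    }


def save_config(path, params: ModelParams, grid: GridSpec | None = None,
                seed: int = 0, experiment: dict | None = None) -> None:
    doc = dict(params.to_dict())
    if grid is not None:
        doc["grid"] = dataclasses.asdict(grid)
    doc["seed"] = seed
    if experiment:
        doc["experiment"] = experiment
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def save_state(path, state: SimulationState) -> None:
    """Write all fields of a simulation state to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        h5.attrs["t"] = state.t
        h5.attrs["dx"] = state.grid.dx
        h5.attrs["dt"] = state.grid.dt
        h5.attrs["params_json"] = json.dumps(state.params.to_dict())
        h5.create_dataset("pattern/chi", data=state.pattern.chi.values)
        h5["pattern"].attrs["d"] = state.pattern.d
        h5["pattern"].attrs["edge_w"] = state.pattern.edge_w
        for i, c in enumerate(state.cells):
            grp = h5.create_group(f"cells/{i}")
            grp.create_dataset("phi", data=c.phi)
            grp.create_dataset("rho", data=c.rho)
            grp.create_dataset("I", data=c.I)


def load_state(path) -> SimulationState:
    with h5py.File(path, "r") as h5:
        params = ModelParams.from_dict(json.loads(h5.attrs["params_json"]))
        chi = np.asarray(h5["pattern/chi"])
        ny, nx = chi.shape
        grid = GridSpec(nx=nx, ny=ny, dx=float(h5.attrs["dx"]),
                        dt=float(h5.attrs["dt"]))
        pattern = Micropattern(
            ScalarField(chi, grid.dx),
            d=float(h5["pattern"].attrs["d"]),
            edge_w=float(h5["pattern"].attrs["edge_w"]))
        cells = []
        i = 0
        while f"cells/{i}" in h5:
            grp = h5[f"cells/{i}"]
            cells.append(CellState(np.asarray(grp["phi"]),
                                   np.asarray(grp["rho"]),
                                   np.asarray(grp["I"])))
            i += 1
        t = float(h5.attrs["t"])
    return SimulationState(cells, pattern, grid, params, t=t)


@dataclass
class RunManifest:
    """What a run was and where its outputs went."""

    params_digest: str
    seed: int
    grid: dict
    outputs: list[str] = field(default_factory=list)
    wall_time_s: float | None = None
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    code_version: str = "cilpf-0.1.0"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def outputs_exist(self) -> bool:
        return all(Path(p).exists() for p in self.outputs)


def write_records(path, records, mode: str = "a") -> None:
    """Append CollisionRecords (or dicts) as JSON lines."""
    with open(path, mode) as fh:
        for rec in records:
            doc = rec.to_dict() if hasattr(rec, "to_dict") else dict(rec)
            fh.write(json.dumps(doc) + "\n")


def read_records(path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
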