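"""Configuration files, VTK output, metrics CSV and run manifests.

Configs are YAML mappings mirroring :class:`ScenarioConfig` (nested
dataclasses as nested mappings); unknown keys are rejected by name.
Fields are written as legacy-VTK ASCII: rectilinear grids
(STRUCTURED_POINTS) for the Eulerian state and UNSTRUCTURED_GRID for the
structure.  Units are CGS in all files (cm, cm/s, dyn/cm^2); reporting
layers convert to mL/mmHg/kPa.  Every run directory receives exactly one
manifest recording the config hash, seed and emitted artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from .scenarios import ScenarioConfig
from .geometry import TestbedParams
from .materials import PassiveParams
from .grid import StaggeredGrid
from .fe import StructureMesh

__all__ = ["read_config", "write_config", "config_to_dict",
           "write_structured_vtk", "write_unstructured_vtk",
           "read_unstructured_vtk", "write_fields", "RunManifest",
           "write_run_outputs", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

_NESTED = {"testbed": TestbedParams, "passive": PassiveParams,
           "leaflet_passive": PassiveParams}


def _field_default(cls, name):
    for f in dataclasses.fields(cls):
        if f.name == name:
            if f.default is not dataclasses.MISSING:
                return f.default
            if f.default_factory is not dataclasses.MISSING:  # type: ignore
                return f.default_factory()
    return None


def _coerce_like(value, default):
    """Coerce a YAML value to the type of the field's default."""
    if isinstance(default, bool):
        return bool(value)
    if isinstance(default, int) and not isinstance(default, bool):
        return int(value)
    if isinstance(default, float):
        return float(value)
    if isinstance(default, tuple):
        return tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                     for v in value)
    return value


def _dataclass_from_dict(cls, data: dict, path="") -> dict:
    """Validated keyword dict for `cls` from a nested mapping."""
    names = {f.name for f in dataclasses.fields(cls)}
    kw = {}
    for key, val in data.items():
        if key not in names:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if key in _NESTED and isinstance(val, dict):
            sub = _NESTED[key]
            kw[key] = sub(**_dataclass_from_dict(sub, val, path + key + "."))
        else:
            kw[key] = _coerce_like(val, _field_default(cls, key))
    return kw


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x
    return clean(d)


def read_config(path) -> ScenarioConfig:
    """Read and validate a scenario configuration file.

    A ``case`` key selects the named case; remaining keys override its
    defaults.  Unknown keys raise with the offending key name; the case
    invariants (e.g. AF implies zero activation) are enforced.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"empty or malformed config file {path}")
    schema = raw.pop("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {schema}")
    case = raw.pop("case", "original")
    over = _dataclass_from_dict(ScenarioConfig, raw)
    return ScenarioConfig.from_case(case, **over)


def write_config(cfg: ScenarioConfig, path):
    d = config_to_dict(cfg)
    d["schema"] = SCHEMA_VERSION
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(cfg: ScenarioConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ------------------------------------------------------------- VTK output

_CELL_TYPE = {"quad4": 9, "tet4": 10, "hex8": 12}


def _pad3(pts):
    pts = np.asarray(pts, float)
    if pts.shape[1] == 3:
        return pts
    return np.column_stack([pts, np.zeros(len(pts))])


def write_unstructured_vtk(path, nodes, elem_type, conn, cell_data=None,
                           point_data=None, comment="atriumfsi structure"):
    """Write a mesh + per-cell/per-point arrays as legacy-VTK ASCII.

    cell_data / point_data: name -> array; (n, 2|3) arrays are written as
    VECTORS, 1D float as SCALARS, 1D int as integer SCALARS.  The comment
    line carries the unit system (CGS).
    """
    nodes3 = _pad3(nodes)
    conn = np.asarray(conn, np.int64)
    lines = ["# vtk DataFile Version 3.0",
             f"{comment} | units: cm (coords), CGS fields",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes3)} double"]
    lines += [" ".join(f"{x:.10g}" for x in p) for p in nodes3]
    k = conn.shape[1]
    lines.append(f"CELLS {len(conn)} {len(conn) * (k + 1)}")
    lines += [f"{k} " + " ".join(map(str, row)) for row in conn]
    lines.append(f"CELL_TYPES {len(conn)}")
    ct = _CELL_TYPE[elem_type]
    lines += [str(ct)] * len(conn)

    def emit(data):
        out = []
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{x:.10g}" for x in _pad3(arr[i:i + 1])[0])
                        for i in range(len(arr))]
            elif arr.dtype.kind in "iu":
                out.append(f"SCALARS {name} int 1")
                out.append("LOOKUP_TABLE default")
                out += [str(int(v)) for v in arr]
            else:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out += [f"{v:.10g}" for v in arr]
        return out

    if cell_data:
        lines.append(f"CELL_DATA {len(conn)}")
        lines += emit(cell_data)
    if point_data:
        lines.append(f"POINT_DATA {len(nodes3)}")
        lines += emit(point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def read_unstructured_vtk(path):
    """Read back files produced by :func:`write_unstructured_vtk`."""
    tokens = Path(path).read_text().splitlines()
    i = tokens.index("DATASET UNSTRUCTURED_GRID")
    n = int(tokens[i + 1].split()[1])
    pts = np.array([[float(x) for x in tokens[i + 2 + j].split()]
                    for j in range(n)])
    i = i + 2 + n
    ncell = int(tokens[i].split()[1])
    conn = np.array([[int(x) for x in tokens[i + 1 + j].split()[1:]]
                     for j in range(ncell)])
    i = i + 1 + ncell
    assert tokens[i].startswith("CELL_TYPES")
    i += 1 + ncell
    data = {"cell": {}, "point": {}}
    section, count = None, 0
    while i < len(tokens):
        line = tokens[i].split()
        if not line:
            i += 1
            continue
        if line[0] == "CELL_DATA":
            section, count = "cell", int(line[1])
            i += 1
        elif line[0] == "POINT_DATA":
            section, count = "point", int(line[1])
            i += 1
        elif line[0] == "VECTORS":
            arr = np.array([[float(x) for x in tokens[i + 1 + j].split()]
                            for j in range(count)])
            data[section][line[1]] = arr
            i += 1 + count
        elif line[0] == "SCALARS":
            name = line[1]
            kind = line[2]
            vals = [tokens[i + 2 + j] for j in range(count)]
            arr = (np.array([int(v) for v in vals]) if kind == "int"
                   else np.array([float(v) for v in vals]))
            data[section][name] = arr
            i += 2 + count
        else:
            i += 1
    return pts, conn, data


def write_structured_vtk(path, grid: StaggeredGrid, comment="atriumfsi fields"):
    """Eulerian snapshot (cell-centred velocity + pressure), legacy ASCII."""
    from .metrics import cell_center_velocity
    if grid.dim != 2:
        raise NotImplementedError("structured writer is 2D")
    nx, ny = grid.n
    uc = cell_center_velocity(grid)
    lines = ["# vtk DataFile Version 3.0",
             f"{comment} | units: cm, cm/s, dyn/cm^2",
             "ASCII", "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx + 1} {ny + 1} 1",
             f"ORIGIN {grid.origin[0]:.10g} {grid.origin[1]:.10g} 0",
             f"SPACING {grid.h:.10g} {grid.h:.10g} {grid.h:.10g}",
             f"CELL_DATA {nx * ny}",
             "SCALARS pressure double 1", "LOOKUP_TABLE default"]
    lines += [f"{v:.10g}" for v in grid.p.T.ravel()]
    lines.append("VECTORS velocity double")
    flat = uc.transpose(1, 0, 2).reshape(-1, 2)
    lines += [f"{v[0]:.10g} {v[1]:.10g} 0" for v in flat]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fields(grid: StaggeredGrid, mesh: StructureMesh, chi, step: int,
                 out_dir, extra_cell_data=None):
    """Write one deterministic, lexicographically ordered snapshot pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fpath = out / f"fluid_{step:06d}.vtk"
    spath = out / f"structure_{step:06d}.vtk"
    write_structured_vtk(fpath, grid)
    cell_data = {}
    if mesh.fibre is not None:
        cell_data["fibre"] = mesh.fibre
    labels = {lab: i for i, lab in enumerate(sorted(set(mesh.region)))}
    cell_data["region"] = np.array([labels[r] for r in mesh.region])
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    write_unstructured_vtk(spath, chi, mesh.elem_type, mesh.conn,
                           cell_data=cell_data)
    return [fpath, spath]


# ---------------------------------------------------------------- manifest


class RunManifest:
    """Provenance record for one output directory."""

    def __init__(self, cfg: ScenarioConfig, seed=None):
        from . import __version__
        self.data = {
            "config_hash": config_hash(cfg),
            "case": cfg.case,
            "code_version": __version__,
            "seed": cfg.seed if seed is None else seed,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "artifacts": [],
        }

    def add(self, path):
        self.data["artifacts"].append(str(Path(path).name))

    def write(self, out_dir):
        p = Path(out_dir) / "manifest.json"
        p.write_text(json.dumps(self.data, indent=2) + "\n")
        return p


def write_run_outputs(bundle, cfg: ScenarioConfig, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest(cfg)
    cpath = out / "config.yaml"
    write_config(cfg, cpath)
    man.add(cpath)
    mpath = out / "metrics.csv"
    bundle.to_csv(mpath)
    man.add(mpath)
    spath = out / "summary.csv"
    bundle.summary_row().to_csv(spath, index=False)
    man.add(spath)
    man.write(out)
    return out
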