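"""Run configuration, provenance and file formats.

One YAML config file with explicit unit suffixes describes a full run
(cell, medium, drive, layout, grid, mc, analysis).  Outputs: extended-XYZ
trajectories, legacy-ASCII VTK structured grids plus an .npz array
container with a JSON header for bit-exact re-import, JSON reports, and a
run manifest with checksums so any run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dielectric import DriveSettings, MediumParams, ShellCellModel
from .energy import Configuration
from .field import ElectrodeLayout, FieldGrid, SimulationGrid
from .mc import MCSettings
from .units import UnitError, parse_quantity

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class AnalysisSettings:
    """Post-processing parameters (deposition time, chain thresholds)."""

    t_dep: float = 180.0                 # s
    chain_z_max: float | None = None     # m; None = whole box
    contact_slack: float | None = None   # m; None = half lattice spacing


@dataclass
class RunConfig:
    """Validated, unit-normalized configuration of one simulation run."""

    cell: ShellCellModel
    medium: MediumParams
    drive: DriveSettings
    layout: ElectrodeLayout
    grid: SimulationGrid
    mc: MCSettings
    analysis: AnalysisSettings
    seed: int = 0
    schema_version: int = SCHEMA_VERSION


# section -> field -> (dimension, default-carrying attribute name)
_SCHEMA = {
    "cell": {
        "radius": ("length", "radius_a"),
        "membrane_thickness": ("length", "membrane_thickness_d"),
        "eps_in_rel": ("dimensionless", "eps_in_rel"),
        "eps_me_rel": ("dimensionless", "eps_me_rel"),
        "sigma_in": ("conductivity", "sigma_in"),
        "sigma_me": ("conductivity", "sigma_me"),
    },
    "medium": {
        "eps_rel": ("dimensionless", "eps_rel"),
        "sigma": ("conductivity", "sigma"),
        "viscosity": ("viscosity", "viscosity"),
        "temperature": ("temperature", "temperature"),
    },
    "drive": {
        "amplitude": ("voltage", "amplitude_V"),
        "frequency": ("frequency", "frequency"),
        "amplitude_convention": (None, "amplitude_convention"),
        "phase_pattern": (None, "phase_pattern"),
    },
    "layout": {
        "half_gap_D": ("length", "half_gap_D"),
        "extent_L": ("length", "extent_L"),
        "edge_convention": (None, "edge_convention"),
        "truncation_margin": ("length", "truncation_margin"),
    },
    "grid": {
        "box": (None, "box"),
        "spacing": ("length", "spacing"),
    },
    "mc": {
        "iterations": (None, "iterations"),
        "seed": (None, "seed"),
        "temperature": ("temperature", "temperature"),
        "move_set": (None, "move_set"),
        "cutoff": ("length", "cutoff"),
        "sampling_interval": (None, "sampling_interval"),
        "time_mode": (None, "time_mode"),
        "acceptance_rule": (None, "acceptance_rule"),
    },
    "analysis": {
        "t_dep": ("time", "t_dep"),
        "chain_z_max": ("length", "chain_z_max"),
        "contact_slack": ("length", "contact_slack"),
    },
}

_SECTION_TYPES = {
    "cell": ShellCellModel,
    "medium": MediumParams,
    "drive": DriveSettings,
    "layout": ElectrodeLayout,
    "grid": SimulationGrid,
    "mc": MCSettings,
    "analysis": AnalysisSettings,
}


def _build_section(name: str, raw: dict):
    schema = _SCHEMA[name]
    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    kwargs = {}
    for key, value in raw.items():
        dim, attr = schema[key]
        if dim is None:
            if key == "box":
                if not isinstance(value, (list, tuple)) or len(value) != 3:
                    raise ConfigError("grid.box must be three lengths")
                value = tuple(parse_quantity(v, "length") for v in value)
            elif key == "phase_pattern":
                value = tuple(int(v) for v in value)
            kwargs[attr] = value
        else:
            try:
                kwargs[attr] = parse_quantity(value, dim)
            except UnitError as exc:
                raise ConfigError(f"{name}.{key}: {exc}") from exc
    try:
        return _SECTION_TYPES[name](**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run file; absent keys take the defaults
    of the MDA-MB-231 / polynomial-electrode reference device."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    known_top = set(_SCHEMA) | {"seed", "schema_version"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    sections = {}
    for name in _SCHEMA:
        sec = raw.get(name, {}) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, sec)
    return RunConfig(seed=int(raw.get("seed", 0)),
                     schema_version=version, **sections)


# serialization uses SI base units so that parse -> dump -> parse is a
# bit-exact identity (scaled units like um are accepted on input only)
_UNIT_OUT = {
    "length": "m",
    "time": "s",
    "frequency": "Hz",
    "voltage": "V",
    "conductivity": "S/m",
    "viscosity": "Pa*s",
    "temperature": "K",
}


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to unit-suffixed YAML (lossless round trip)."""
    out: dict = {"schema_version": cfg.schema_version, "seed": cfg.seed}
    for name, schema in _SCHEMA.items():
        section_obj = getattr(cfg, name)
        sec_out = {}
        for key, (dim, attr) in schema.items():
            value = getattr(section_obj, attr)
            if value is None:
                continue
            if key == "box":
                sec_out[key] = [f"{v!r} m" for v in value]
            elif key == "phase_pattern":
                sec_out[key] = list(value)
            elif dim is None or dim == "dimensionless":
                sec_out[key] = value
            else:
                sec_out[key] = f"{value!r} {_UNIT_OUT[dim]}"
        out[name] = sec_out
    return yaml.safe_dump(out, sort_keys=False)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(dump_config(cfg))


# ---------------------------------------------------------------------------
# extended XYZ trajectories
# ---------------------------------------------------------------------------


def write_snapshot(config_or_positions, grid: SimulationGrid, stream,
                   comment: str = "", element: str = "C") -> None:
    """Write one extended-XYZ frame (coordinates in micrometres)."""
    if isinstance(config_or_positions, Configuration):
        pos = config_or_positions.positions
    else:
        pos = np.asarray(config_or_positions)
    n = pos.shape[0]
    stream.write(f"{n}\n")
    stream.write(comment.replace("\n", " ") + "\n")
    if n:
        xs = grid.x[pos[:, 0]] * 1e6
        ys = grid.y[pos[:, 1]] * 1e6
        zs = grid.z[pos[:, 2]] * 1e6
        for x, y, z in zip(xs, ys, zs):
            stream.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory(traj, grid: SimulationGrid, path) -> None:
    """Write all snapshots of a trajectory as a multi-frame extended XYZ."""
    with open(path, "w") as fh:
        for s in range(traj.positions.shape[0]):
            comment = (f"iteration={traj.iterations[s]} "
                       f"time_s={traj.times[s]:.6e} "
                       f"dep_energy_J={traj.dep_energy[s]:.9e} "
                       f"pair_energy_J={traj.pair_energy[s]:.9e}")
            write_snapshot(traj.positions[s], grid, fh, comment=comment)


def read_xyz_frames(path):
    """Read frames back as a list of (comment, (n,3) positions in um)."""
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().rstrip("\n")
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(v) for v in parts[1:4]]
            frames.append((comment, coords))
    return frames


# ---------------------------------------------------------------------------
# field export
# ---------------------------------------------------------------------------


def export_field(fg: FieldGrid, basepath) -> list[Path]:
    """Export a solved field as legacy-ASCII VTK plus an .npz container.

    ``basepath`` without extension; writes ``<base>.vtk``, ``<base>.npz``
    and ``<base>.json`` (axis order, spacing and units metadata).  The .npz
    round-trips bit-exactly through :func:`import_field`.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = fg.grid.shape
    d_um = fg.grid.spacing * 1e6
    vtk_path = base.with_suffix(".vtk")
    with open(vtk_path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("depmc field export\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {fg.grid.x[0] * 1e6:.6f} {fg.grid.y[0] * 1e6:.6f} "
                 f"{fg.grid.z[0] * 1e6:.6f}\n")
        fh.write(f"SPACING {d_um:.6f} {d_um:.6f} {d_um:.6f}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS potential_V double 1\nLOOKUP_TABLE default\n")
        # VTK structured points vary x fastest -> transpose to (z, y, x)
        np.savetxt(fh, fg.potential.T.reshape(-1, 1), fmt="%.9e")
        if fg.erms_sq is not None:
            fh.write("SCALARS erms_sq_V2_per_m2 double 1\n"
                     "LOOKUP_TABLE default\n")
            np.savetxt(fh, fg.erms_sq.T.reshape(-1, 1), fmt="%.9e")

    npz_path = base.with_suffix(".npz")
    arrays = {"potential": fg.potential}
    for name in ("erms", "erms_sq", "grad_erms_sq"):
        arr = getattr(fg, name)
        if arr is not None:
            arrays[name] = arr
    if fg.electrode_sign is not None:
        arrays["electrode_sign"] = fg.electrode_sign
    np.savez(npz_path, **arrays)

    header = {
        "axis_order": ["x", "y", "z"],
        "spacing_um": d_um,
        "box_um": [b * 1e6 for b in fg.grid.box],
        "shape": [nx, ny, nz],
        "units": {"potential": "V", "erms": "V/m",
                  "erms_sq": "V^2/m^2", "grad_erms_sq": "V^2/m^3"},
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(header, indent=1))
    return [vtk_path, npz_path, json_path]


def import_field(basepath) -> FieldGrid:
    """Re-import a field exported by :func:`export_field` (bit-exact)."""
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    grid = SimulationGrid(tuple(b * 1e-6 for b in header["box_um"]),
                          header["spacing_um"] * 1e-6)
    data = np.load(base.with_suffix(".npz"))
    fg = FieldGrid(grid=grid, potential=data["potential"])
    for name in ("erms", "erms_sq", "grad_erms_sq", "electrode_sign"):
        if name in data:
            setattr(fg, name, data[name])
    return fg


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, cfg: RunConfig, files) -> Path:
    """Write a run manifest (config, version, seed, checksums)."""
    outdir = Path(outdir)
    manifest = {
        "code_version": __version__,
        "schema_version": cfg.schema_version,
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_yaml": dump_config(cfg),
        "outputs": {str(Path(f).name): _sha256(f) for f in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def verify_manifest(outdir) -> bool:
    """Check every file listed in a manifest against its checksum."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(_sha256(outdir / name) == digest
               for name, digest in manifest["outputs"].items())
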