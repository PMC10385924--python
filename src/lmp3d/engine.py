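"""Orchestration: parse inputs, compute descriptors per molecule per frame,
and write one ``molecule_<molID>.csv`` per molecule plus a run manifest.

The work unit is (molecule, frame); results are assembled in a fixed order
regardless of how work was scheduled, so any worker count produces
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

from . import __version__
from . import desc_cpsa, desc_field3d, desc_geometric, desc_getaway, desc_topo3d, desc_whim
from .errors import ZeroVolume
from .lammps_io import DumpFrame, check_consistency, parse_data, parse_dump
from .molecular_model import (
    SystemTopology,
    build_topology,
    make_snapshot,
    unwrap_frame,
)

#: g/mol per A^3 -> g/cm^3 (10^24 / Avogadro's number).
DENSITY_FACTOR = 1.66054

SET_NAMES = {
    1: "topo3d",
    2: "geometric",
    3: "getaway",
    4: "cpsa",
    5: "whim",
    6: "field3d",
}


def density(frame: DumpFrame, topo: SystemTopology) -> float:
    """System mass density in g/cm^3 from the frame's box volume."""
    volume = 1.0
    for lo, hi in frame.box:
        volume *= hi - lo
    if volume <= 0:
        raise ZeroVolume(f"box volume {volume} A^3")
    return topo.total_mass * DENSITY_FACTOR / volume


@dataclass
class RunConfig:
    data_path: str
    traj_path: str
    sets: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    workers: int = 0  # 0 -> all detected processors
    out_dir: str = "."
    stride: int = 1
    probe_radius: float = desc_cpsa.DEFAULT_PROBE
    sasa_points: int = desc_cpsa.DEFAULT_POINTS
    polar_charge_threshold: float = desc_cpsa.POLAR_CHARGE_THRESHOLD

    def __post_init__(self):
        self.sets = tuple(sorted(set(self.sets)))
        if not self.sets or any(s not in SET_NAMES for s in self.sets):
            raise ValueError(f"sets must be a non-empty subset of 1..6: {self.sets}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.workers < 0:
            raise ValueError("workers must be >= 0")


def compute_blocks(snapshot, sets, config: RunConfig | None = None) -> dict[str, float]:
    """Descriptor columns for one molecule-frame, in fixed set order."""
    out: dict[str, float] = {}
    for s in sorted(sets):
        if s == 1:
            out.update(desc_topo3d.topo3d(snapshot))
        elif s == 2:
            out.update(desc_geometric.geometric(snapshot))
        elif s == 3:
            out.update(desc_getaway.getaway(snapshot))
        elif s == 4:
            kwargs = {}
            if config is not None:
                kwargs = dict(
                    probe=config.probe_radius,
                    n_points=config.sasa_points,
                    polar_threshold=config.polar_charge_threshold,
                )
            out.update(desc_cpsa.cpsa(snapshot, **kwargs))
        elif s == 5:
            out.update(desc_whim.whim(snapshot))
        elif s == 6:
            out.update(desc_field3d.field3d(snapshot))
    return out


def _work_unit(args):
    topo_mol, timestep, coords, sets, config = args
    snap = make_snapshot(topo_mol, timestep, coords)
    return compute_blocks(snap, sets, config)


@dataclass
class RunResult:
    csv_paths: dict[int, str]
    manifest_path: str
    n_frames: int
    columns: list[str] = field(default_factory=list)


def _format_value(v: float) -> str:
    return repr(float(v))


def _file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> RunResult:
    """Full pipeline: parse, check, unwrap, compute, write CSVs + manifest."""
    data = parse_data(config.data_path)
    frames = parse_dump(config.traj_path)
    topo = build_topology(data)
    check_consistency(data, frames)
    frames = frames[:: config.stride]

    mol_ids = topo.molecule_ids
    units = []
    meta = []  # (mol_id, timestep, rho) in output order
    for frame in frames:
        rho = density(frame, topo)
        coords_by_mol = unwrap_frame(frame, topo)
        for mol_id in mol_ids:
            units.append(
                (
                    topo.molecules[mol_id],
                    frame.timestep,
                    coords_by_mol[mol_id],
                    config.sets,
                    config,
                )
            )
            meta.append((mol_id, frame.timestep, rho))

    workers = config.workers or (os.cpu_count() or 1)
    if workers == 1 or len(units) <= 1:
        results = [_work_unit(u) for u in units]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_work_unit, units, chunksize=1))

    columns = list(results[0].keys()) if results else []
    rows_by_mol: dict[int, list[str]] = {m: [] for m in mol_ids}
    for (mol_id, timestep, rho), block in zip(meta, results):
        row = [str(timestep), _format_value(rho)] + [
            _format_value(block[c]) for c in columns
        ]
        rows_by_mol[mol_id].append(",".join(row))

    os.makedirs(config.out_dir, exist_ok=True)
    header = ",".join(["timestep", "density"] + columns)
    csv_paths: dict[int, str] = {}
    for mol_id in mol_ids:
        path = os.path.join(config.out_dir, f"molecule_{mol_id}.csv")
        tmp = path + ".tmp"
        with open(tmp, "w", newline="\n") as fh:
            fh.write(header + "\n")
            fh.write("\n".join(rows_by_mol[mol_id]) + "\n")
        os.replace(tmp, path)  # atomic rename guards partial writes
        csv_paths[mol_id] = path

    catalogue_hash = hashlib.sha256(
        ("\n".join(["timestep", "density"] + columns)).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "inputs": {
            "data": {"path": config.data_path, "sha256": _file_sha256(config.data_path)},
            "trajectory": {
                "path": config.traj_path,
                "sha256": _file_sha256(config.traj_path),
            },
        },
        "config": {
            "sets": list(config.sets),
            "workers": workers,
            "stride": config.stride,
            "probe_radius": config.probe_radius,
            "sasa_points": config.sasa_points,
            "polar_charge_threshold": config.polar_charge_threshold,
        },
        "n_frames": len(frames),
        "n_molecules": len(mol_ids),
        "descriptor_catalogue_sha256": catalogue_hash,
        "outputs": [os.path.basename(p) for p in csv_paths.values()],
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    tmp = manifest_path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, manifest_path)
    return RunResult(
        csv_paths=csv_paths,
        manifest_path=manifest_path,
        n_frames=len(frames),
        columns=["timestep", "density"] + columns,
    )
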