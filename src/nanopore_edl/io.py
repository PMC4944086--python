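"""Readers and writers: extended XYZ configurations/trajectories, PDB
snapshots, and TSV profiles/energy logs.

The XYZ dialect is self-delimiting (each frame carries its own header) so
a truncated file parses up to the last complete frame.  The comment line
of every frame holds a JSON object with the geometry, run metadata and
per-frame state, which makes a trajectory file self-contained.  Wall
charges travel as trailing ``WALLQ`` records of every frame.  All writes
go through a write-temp-then-rename step so partial output never
masquerades as complete.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .sampler import Trajectory
from .system import PoreGeometry, SystemConfiguration

__all__ = [
    "atomic_write_text",
    "write_xyz_config",
    "read_xyz_config",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_pdb",
    "profile_to_tsv",
    "write_energy_log",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_lines(
    species: list[str],
    pos: np.ndarray,
    vel: np.ndarray | None,
    wall_pos: np.ndarray,
    comment: dict[str, Any],
) -> list[str]:
    n = len(species) + len(wall_pos)
    lines = [str(n), json.dumps(comment, sort_keys=True)]
    for i, s in enumerate(species):
        row = f"{s} {pos[i, 0]:.8f} {pos[i, 1]:.8f} {pos[i, 2]:.8f}"
        if vel is not None:
            row += f" {vel[i, 0]:.10e} {vel[i, 1]:.10e} {vel[i, 2]:.10e}"
        lines.append(row)
    for w in wall_pos:
        lines.append(f"WALLQ {w[0]:.8f} {w[1]:.8f} {w[2]:.8f}")
    return lines


def _geometry_meta(geo: PoreGeometry) -> dict[str, float]:
    return {"r_n": geo.r_n, "l_z": geo.l_z}


def write_xyz_config(config: SystemConfiguration, path: str | Path) -> None:
    """One-frame extended XYZ (with velocity columns) of a configuration."""
    comment = {
        **_geometry_meta(config.geometry),
        "mol_id": config.mol_id.tolist(),
        "metadata": _jsonable(config.metadata),
    }
    lines = _frame_lines(config.species, config.positions, config.velocities, config.wall_positions, comment)
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_xyz_config(path: str | Path) -> SystemConfiguration:
    frames = _read_xyz_frames(path)
    if not frames:
        raise ValueError(f"{path}: no complete frame found")
    species, pos, vel, wall, comment = frames[0]
    mol = np.asarray(comment.get("mol_id", list(range(len(species)))), dtype=np.int64)
    geo = PoreGeometry(r_n=comment["r_n"], l_z=comment["l_z"])
    return SystemConfiguration(
        species=species,
        positions=pos,
        velocities=vel,
        mol_id=mol,
        wall_positions=wall,
        geometry=geo,
        metadata=comment.get("metadata", {}),
    )


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Multi-frame XYZ; static metadata rides in every frame header."""
    lines: list[str] = []
    static = {
        **_geometry_meta(traj.geometry),
        "mol_id": traj.mol_id.tolist(),
        "metadata": _jsonable(traj.metadata),
    }
    for k in range(traj.n_frames):
        comment = dict(static)
        comment.update(
            frame=k,
            temperature=float(traj.temperatures[k]),
            potential=float(traj.potentials[k]),
            total_energy=float(traj.total_energies[k]),
        )
        lines.extend(_frame_lines(traj.species, traj.frames[k], None, traj.wall_positions, comment))
    if traj.n_frames == 0:
        # header-only file: zero atoms, metadata intact
        lines = ["0", json.dumps(dict(static, frame=-1), sort_keys=True)]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    frames = _read_xyz_frames(path)
    if not frames:
        raise ValueError(f"{path}: no complete frame found")
    species, _, _, wall, comment0 = frames[0]
    geo = PoreGeometry(r_n=comment0["r_n"], l_z=comment0["l_z"])
    if comment0.get("frame") == -1 and not species:
        return Trajectory(
            frames=np.zeros((0, 0, 3)),
            temperatures=np.zeros(0),
            potentials=np.zeros(0),
            total_energies=np.zeros(0),
            species=[],
            mol_id=np.zeros(0, dtype=np.int64),
            wall_positions=np.zeros((0, 3)),
            wall_charges=np.zeros(0),
            geometry=geo,
            metadata=comment0.get("metadata", {}),
        )
    pos = np.stack([f[1] for f in frames])
    temps = np.array([f[4].get("temperature", np.nan) for f in frames])
    pots = np.array([f[4].get("potential", np.nan) for f in frames])
    etots = np.array([f[4].get("total_energy", np.nan) for f in frames])
    mol = np.asarray(comment0.get("mol_id", list(range(len(species)))), dtype=np.int64)
    return Trajectory(
        frames=pos,
        temperatures=temps,
        potentials=pots,
        total_energies=etots,
        species=species,
        mol_id=mol,
        wall_positions=wall,
        wall_charges=np.full(len(wall), -1.0),
        geometry=geo,
        metadata=comment0.get("metadata", {}),
    )


def _read_xyz_frames(path: str | Path):
    """Parse complete frames; silently stop at a truncated tail."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            break
        if i + 2 + n > len(lines):
            break
        try:
            comment = json.loads(lines[i + 1]) if lines[i + 1].strip().startswith("{") else {}
        except json.JSONDecodeError:
            break
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            break
        species: list[str] = []
        pos_rows: list[list[float]] = []
        vel_rows: list[list[float]] = []
        wall_rows: list[list[float]] = []
        ok = True
        for row in body:
            parts = row.split()
            if len(parts) not in (4, 7):
                ok = False
                break
            name = parts[0]
            vals = [float(v) for v in parts[1:]]
            if name == "WALLQ":
                wall_rows.append(vals[:3])
            else:
                species.append(name)
                pos_rows.append(vals[:3])
                vel_rows.append(vals[3:6] if len(vals) >= 6 else [0.0, 0.0, 0.0])
        if not ok:
            break
        out.append(
            (
                species,
                np.asarray(pos_rows).reshape(len(species), 3),
                np.asarray(vel_rows).reshape(len(species), 3),
                np.asarray(wall_rows).reshape(len(wall_rows), 3),
                comment,
            )
        )
        i = i + 2 + n
    return out


def write_pdb(config: SystemConfiguration, path: str | Path) -> None:
    """PDB snapshot (via MDAnalysis) with wall charges as a WAL residue."""
    import warnings

    import MDAnalysis as mda

    n_mobile = config.n_particles
    n_total = n_mobile + config.n_wall_charges
    if n_total == 0:
        atomic_write_text(path, "END\n")
        return
    n_mol = len(np.unique(config.mol_id)) if n_mobile else 0
    resindex = np.concatenate(
        [
            np.unique(config.mol_id, return_inverse=True)[1] if n_mobile else np.zeros(0, dtype=int),
            np.full(config.n_wall_charges, n_mol, dtype=int),
        ]
    )
    n_res = n_mol + (1 if config.n_wall_charges else 0)
    u = mda.Universe.empty(
        n_total, n_residues=max(1, n_res), atom_resindex=resindex,
        residue_segindex=np.zeros(max(1, n_res), dtype=int), trajectory=True,
    )
    names = [s.replace("+", "").replace("-", "") for s in config.species] + ["WQ"] * config.n_wall_charges
    resnames = []
    for m in np.unique(config.mol_id) if n_mobile else []:
        first = config.species[int(np.nonzero(config.mol_id == m)[0][0])]
        resnames.append({"O": "SOL", "H": "SOL", "Na+": "NA", "Cl-": "CL"}.get(first, "UNK"))
    if config.n_wall_charges:
        resnames.append("WAL")
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames or ["UNK"])
    pos = np.vstack([config.positions, config.wall_positions]) if n_total else np.zeros((0, 3))
    u.atoms.positions = pos
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp.pdb")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(tmp))
    os.replace(tmp, path)


def profile_to_tsv(x: np.ndarray, columns: dict[str, np.ndarray], path: str | Path, x_name: str = "r_A") -> None:
    """Write aligned columns as TSV (first column ``x``)."""
    df = pd.DataFrame({x_name: x, **columns})
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.8g"))


def write_energy_log(traj: Trajectory, path: str | Path) -> None:
    """TSV log: sampled step, T (K), potential and total energy (kJ/mol)."""
    interval = int(traj.metadata.get("sample_interval", 1))
    steps = (np.arange(traj.n_frames) + 1) * interval
    profile_to_tsv(
        steps,
        {
            "T_K": traj.temperatures,
            "U_kJ_mol": traj.potentials,
            "E_total_kJ_mol": traj.total_energies,
        },
        path,
        x_name="step",
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
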