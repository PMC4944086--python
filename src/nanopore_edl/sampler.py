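"""Equilibrium sampling: explicit-water MD and primitive-model MC runs.

``run(config, spec)`` produces a :class:`Trajectory` of production frames
after discarding equilibration.  The MD mode integrates Newton's equations
with velocity Verlet at a 2 fs step, keeps waters rigid with SHAKE/RATTLE,
and drives the temperature to 298.0 K with a Berendsen thermostat
(tau = 0.1 ps).  The MC mode drops the waters, keeps ions and wall charges
in a dielectric continuum, and samples Metropolis displacement moves.
Both modes are bitwise-deterministic for a fixed (config, spec) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import KB, WATER_EPS_R
from .engine import ParticleArrays, _pair_kernel, _wall_coulomb_kernel, steele_energy_forces
from .integrators import (
    SHAKE_MAX_ITER,
    SHAKE_TOL,
    ConstraintError,
    berendsen_lambda,
    instantaneous_temperature,
    kinetic_energy,
    rattle_velocities,
    shake_positions,
    water_start_indices,
)
from .constants import ACCEL_FACTOR
from .montecarlo import mc_sweep_chunk, mc_total_energy
from .system import PoreGeometry, SystemConfiguration

__all__ = ["RunSpec", "Trajectory", "IntegrationError", "run"]


class IntegrationError(RuntimeError):
    """Dynamics blew up (particle reached the wall) or constraints failed."""


@dataclass(frozen=True)
class RunSpec:
    """Sampling protocol.

    Defaults follow the reference protocol (dt = 2 fs, T0 = 298.0 K,
    tau_T = 0.1 ps); run lengths are configurable so the same protocol
    scales from desk-size validation runs to the full-length schedule.
    """

    dt: float = 2.0  # fs
    t0: float = 298.0  # K
    tau_t: float = 0.1  # ps
    n_equil_steps: int = 1000
    n_prod_steps: int = 4000
    sample_interval: int = 100
    mode: str = "md_explicit"  # or "mc_primitive"
    rng_seed: int = 0
    # Berendsen coupling during production; equilibration is always
    # thermostatted (NVE measurements start from an equilibrated state)
    thermostat: bool = True
    coulomb: str = "cutoff_rf"  # md mode: "cutoff_rf" or "bare"
    r_cut: float | None = None
    mc_step: float = 2.0  # Å, MC displacement cube edge
    eps_r: float = WATER_EPS_R  # continuum permittivity of the MC mode
    n_min_steps: int = 300  # capped steepest-descent steps before MD

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t0 <= 0:
            raise ValueError("dt and t0 must be positive")
        if self.tau_t * 1000.0 < self.dt:
            raise ValueError("tau_T must be at least one time step")
        if self.mode not in ("md_explicit", "mc_primitive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


@dataclass
class Trajectory:
    """Time-ordered production frames plus per-frame state records."""

    frames: np.ndarray  # (n_frames, n_particles, 3)
    temperatures: np.ndarray  # (n_frames,)
    potentials: np.ndarray  # (n_frames,) kJ/mol
    total_energies: np.ndarray  # (n_frames,) kJ/mol
    species: list[str]
    mol_id: np.ndarray
    wall_positions: np.ndarray
    wall_charges: np.ndarray
    geometry: PoreGeometry
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return len(self.species)

    def charges(self, forcefield) -> np.ndarray:
        return np.array([forcefield.charge_of(s) for s in self.species])


def _md_forces(pos, arrays: ParticleArrays, geo: PoreGeometry, spec: RunSpec):
    use_rf = spec.coulomb == "cutoff_rf"
    rc = spec.r_cut if spec.r_cut is not None else min(10.0, 0.5 * geo.l_z)
    rc2 = rc * rc if use_rf else 0.0
    e1, f1, min_r2 = _pair_kernel(
        pos, arrays.charge, arrays.sigma, arrays.epsilon, arrays.mol_id,
        geo.l_z, True, rc2, use_rf, 1.0,
    )
    e2, f2 = _wall_coulomb_kernel(
        pos, arrays.charge, arrays.wall_pos, arrays.wall_q,
        geo.l_z, True, rc2, use_rf, 1.0,
    )
    e3, f3 = steele_energy_forces(pos, arrays, geo.r_n)
    return e1 + e2 + e3, f1 + f2 + f3


def _wrap_by_molecule(pos: np.ndarray, mol_id: np.ndarray, l_z: float) -> np.ndarray:
    """Shift whole molecules so their first site's z lies in [0, l_z)."""
    out = pos.copy()
    first = np.unique(mol_id, return_index=True)[1]
    for i0 in first:
        sel = mol_id == mol_id[i0]
        shift = np.floor(out[i0, 2] / l_z) * l_z
        out[sel, 2] -= shift
    return out


def _run_md(config: SystemConfiguration, spec: RunSpec) -> Trajectory:
    geo = config.geometry
    arrays = ParticleArrays.from_config(config)
    pos = config.positions.copy()
    vel = config.velocities.copy()
    masses = arrays.mass
    inv_mass = 1.0 / masses
    wstart = water_start_indices(config.species, arrays.mol_id)
    n_water = len(wstart)
    ndof = max(1, 3 * config.n_particles - 3 - 3 * n_water)
    d_oh = config.forcefield.water.r_oh
    d_hh = config.forcefield.water.r_hh
    dt = spec.dt

    # make the initial state consistent with the rigid-water constraints
    if n_water:
        fail = shake_positions(pos, pos.copy(), np.zeros_like(vel), inv_mass, wstart, d_oh, d_hh, 0.0, SHAKE_TOL, SHAKE_MAX_ITER)
        fail += rattle_velocities(pos, vel, inv_mass, wstart, SHAKE_TOL, SHAKE_MAX_ITER)
        if fail:
            raise ConstraintError("initial water constraint failed")

    # relax build contacts: steepest descent with a displacement cap, the
    # rigid-water constraint re-imposed after every move
    cap = 0.05  # Å
    for _ in range(spec.n_min_steps):
        _, f = _md_forces(pos, arrays, geo, spec)
        fmax = np.abs(f).max()
        if fmax < 100.0:  # kJ/(mol Å): thermal-scale forces, done
            break
        step_len = cap / fmax
        pos_new = pos + step_len * f
        if n_water:
            shake_positions(pos_new, pos, np.zeros_like(vel), inv_mass, wstart, d_oh, d_hh, 0.0, SHAKE_TOL, SHAKE_MAX_ITER)
        r2 = pos_new[:, 0] ** 2 + pos_new[:, 1] ** 2
        if np.any(r2 >= geo.r_n**2):
            break  # keep the previous in-bounds state
        pos = pos_new

    u, forces = _md_forces(pos, arrays, geo, spec)

    n_frames = spec.n_prod_steps // spec.sample_interval
    frames = np.zeros((n_frames, config.n_particles, 3))
    temps = np.zeros(n_frames)
    pots = np.zeros(n_frames)
    etots = np.zeros(n_frames)
    k = 0
    total = spec.n_equil_steps + spec.n_prod_steps
    for step in range(total):
        v_half = vel + 0.5 * dt * forces * (ACCEL_FACTOR * inv_mass)[:, None]
        pos_new = pos + dt * v_half
        vel = v_half
        if n_water:
            fail = shake_positions(pos_new, pos, vel, inv_mass, wstart, d_oh, d_hh, dt, SHAKE_TOL, SHAKE_MAX_ITER)
            if fail:
                raise IntegrationError(f"SHAKE failed at step {step}")
        r2 = pos_new[:, 0] ** 2 + pos_new[:, 1] ** 2
        bad = np.nonzero(r2 >= geo.r_n**2)[0]
        if len(bad):
            raise IntegrationError(f"particle {bad[0]} reached the wall at step {step}")
        try:
            u, f_new = _md_forces(pos_new, arrays, geo, spec)
        except ValueError as exc:
            raise IntegrationError(f"force evaluation failed at step {step}: {exc}") from exc
        vel = vel + 0.5 * dt * f_new * (ACCEL_FACTOR * inv_mass)[:, None]
        if n_water:
            rattle_velocities(pos_new, vel, inv_mass, wstart, SHAKE_TOL, SHAKE_MAX_ITER)
        pos, forces = pos_new, f_new
        if spec.thermostat or step < spec.n_equil_steps:
            t_inst = instantaneous_temperature(vel, masses, ndof)
            if t_inst > 0:
                vel *= berendsen_lambda(t_inst, spec.t0, dt, spec.tau_t)
        if step >= spec.n_equil_steps and (step - spec.n_equil_steps + 1) % spec.sample_interval == 0:
            frames[k] = _wrap_by_molecule(pos, arrays.mol_id, geo.l_z)
            temps[k] = instantaneous_temperature(vel, masses, ndof)
            pots[k] = u
            etots[k] = u + kinetic_energy(vel, masses)
            k += 1

    return Trajectory(
        frames=frames,
        temperatures=temps,
        potentials=pots,
        total_energies=etots,
        species=list(config.species),
        mol_id=arrays.mol_id.copy(),
        wall_positions=arrays.wall_pos.copy(),
        wall_charges=arrays.wall_q.copy(),
        geometry=geo,
        metadata=_metadata(config, spec),
    )


def _strip_waters(config: SystemConfiguration) -> SystemConfiguration:
    keep = [i for i, s in enumerate(config.species) if s not in ("O", "H")]
    idx = np.asarray(keep, dtype=int)
    return SystemConfiguration(
        species=[config.species[i] for i in keep],
        positions=config.positions[idx] if len(idx) else np.zeros((0, 3)),
        velocities=config.velocities[idx] if len(idx) else np.zeros((0, 3)),
        mol_id=np.arange(len(idx)),
        wall_positions=config.wall_positions,
        geometry=config.geometry,
        forcefield=config.forcefield,
        metadata=dict(config.metadata),
    )


def _run_mc(config: SystemConfiguration, spec: RunSpec) -> Trajectory:
    ions = _strip_waters(config)
    geo = ions.geometry
    arrays = ParticleArrays.from_config(ions)
    pos = ions.positions.copy()
    n = len(pos)
    beta = 1.0 / (KB * spec.t0)
    inv_eps = 1.0 / spec.eps_r
    rng = np.random.default_rng(spec.rng_seed)
    delta = arrays.steele_delta

    def chunk(n_moves: int) -> int:
        if n_moves == 0 or n == 0:
            return 0
        rand = rng.random((n_moves, 4))
        idx = rng.integers(0, n, size=n_moves)
        return mc_sweep_chunk(
            pos, arrays.charge, arrays.sigma, arrays.epsilon,
            arrays.steele_a, arrays.steele_s, delta,
            arrays.wall_pos, arrays.wall_q,
            geo.r_n, geo.l_z, beta, inv_eps, spec.mc_step, rand, idx,
        )

    chunk(spec.n_equil_steps)
    n_frames = spec.n_prod_steps // spec.sample_interval
    frames = np.zeros((n_frames, n, 3))
    temps = np.full(n_frames, spec.t0)
    pots = np.zeros(n_frames)
    n_accept = 0
    for k in range(n_frames):
        n_accept += chunk(spec.sample_interval)
        frames[k] = pos
        if n:
            pots[k] = mc_total_energy(
                pos, arrays.charge, arrays.sigma, arrays.epsilon,
                arrays.steele_a, arrays.steele_s, delta,
                arrays.wall_pos, arrays.wall_q, geo.r_n, geo.l_z, inv_eps,
            )
    # leftover moves that do not fill a full sampling interval
    chunk(spec.n_prod_steps - n_frames * spec.sample_interval)

    meta = _metadata(ions, spec)
    meta["mc_acceptance"] = n_accept / max(1, n_frames * spec.sample_interval)
    return Trajectory(
        frames=frames,
        temperatures=temps,
        potentials=pots,
        total_energies=pots.copy(),
        species=list(ions.species),
        mol_id=np.arange(n),
        wall_positions=arrays.wall_pos.copy(),
        wall_charges=arrays.wall_q.copy(),
        geometry=geo,
        metadata=meta,
    )


def _metadata(config: SystemConfiguration, spec: RunSpec) -> dict[str, Any]:
    meta = dict(config.metadata)
    meta.update(
        {
            "mode": spec.mode,
            "rng_seed": spec.rng_seed,
            "dt_fs": spec.dt,
            "t0_k": spec.t0,
            "tau_t_ps": spec.tau_t,
            "n_equil_steps": spec.n_equil_steps,
            "n_prod_steps": spec.n_prod_steps,
            "sample_interval": spec.sample_interval,
            "sigma_s": config.sigma_s,
            "r_n": config.geometry.r_n,
            "l_z": config.geometry.l_z,
        }
    )
    return meta


def run(config: SystemConfiguration, spec: RunSpec) -> Trajectory:
    """Equilibrate then sample; returns the production trajectory."""
    if spec.mode == "md_explicit":
        return _run_md(config, spec)
    return _run_mc(config, spec)
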