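"""Velocity-Verlet integration, Berendsen thermostatting, and rigid-water
distance constraints (iterative SHAKE/RATTLE).

Internal units as in :mod:`nanopore_edl.constants`: positions Å, velocities
Å/fs, forces kJ/(mol Å), masses g/mol.  The force/mass -> acceleration
conversion factor is applied inside the steppers.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import ACCEL_FACTOR, KB, KINETIC_FACTOR

__all__ = [
    "berendsen_lambda",
    "velocity_verlet_step",
    "kinetic_energy",
    "instantaneous_temperature",
    "constrain_water",
    "ConstraintError",
]

SHAKE_TOL = 1.0e-10  # relative on squared distances
SHAKE_MAX_ITER = 500


class ConstraintError(RuntimeError):
    """Water constraint iteration failed to converge."""


def berendsen_lambda(t_inst: float, t0: float, dt_fs: float, tau_ps: float) -> float:
    """Weak-coupling velocity scale factor sqrt(1 + (dt/tau)(T0/T - 1)).

    ``tau_ps`` is the coupling time constant in ps.  Undefined at zero
    instantaneous temperature.
    """
    if t_inst <= 0.0:
        raise ValueError("Berendsen scaling undefined for non-positive temperature")
    tau_fs = tau_ps * 1000.0
    return math.sqrt(1.0 + (dt_fs / tau_fs) * (t0 / t_inst - 1.0))


def kinetic_energy(vel: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in kJ/mol."""
    return 0.5 * KINETIC_FACTOR * float(np.sum(masses[:, None] * vel**2))


def instantaneous_temperature(vel: np.ndarray, masses: np.ndarray, ndof: int) -> float:
    """2 KE / (kB ndof); the caller supplies the constrained DOF count."""
    if ndof <= 0:
        return 0.0
    return 2.0 * kinetic_energy(vel, masses) / (KB * ndof)


def velocity_verlet_step(pos, vel, forces, masses, dt, force_fn):
    """One unconstrained velocity-Verlet step (half-kick, drift, half-kick).

    ``force_fn(pos) -> forces`` evaluates forces at the drifted positions.
    Returns ``(pos', vel', forces')``.  Time-reversible: stepping with
    ``-dt`` from the result recovers the input to round-off.
    """
    masses = np.asarray(masses, dtype=float)
    inv_m = ACCEL_FACTOR / masses
    v_half = vel + 0.5 * dt * forces * inv_m[:, None]
    pos_new = pos + dt * v_half
    f_new = force_fn(pos_new)
    v_new = v_half + 0.5 * dt * f_new * inv_m[:, None]
    return pos_new, v_new, f_new


@njit(cache=True)
def shake_positions(pos_new, pos_ref, vel, inv_mass, water_start, d_oh, d_hh, dt, tol, max_iter):
    """SHAKE position correction for rigid three-site waters.

    Constraint forces act along the pre-drift (reference) bond vectors;
    velocities receive the matching impulse so the step stays consistent.
    Returns the number of molecules that failed to converge.
    """
    n_fail = 0
    d0s = np.empty(3)
    d0s[0] = d_oh
    d0s[1] = d_oh
    d0s[2] = d_hh
    for w in range(water_start.shape[0]):
        o = water_start[w]
        converged = False
        for _ in range(max_iter):
            done = True
            for c in range(3):
                if c == 0:
                    a, b = o, o + 1
                elif c == 1:
                    a, b = o, o + 2
                else:
                    a, b = o + 1, o + 2
                d0 = d0s[c]
                dx = pos_new[a, 0] - pos_new[b, 0]
                dy = pos_new[a, 1] - pos_new[b, 1]
                dz = pos_new[a, 2] - pos_new[b, 2]
                diff = dx * dx + dy * dy + dz * dz - d0 * d0
                if abs(diff) > tol * d0 * d0:
                    done = False
                    sx = pos_ref[a, 0] - pos_ref[b, 0]
                    sy = pos_ref[a, 1] - pos_ref[b, 1]
                    sz = pos_ref[a, 2] - pos_ref[b, 2]
                    dot = dx * sx + dy * sy + dz * sz
                    if abs(dot) < 1.0e-12:
                        # degenerate (near-orthogonal reference); fall back
                        # to the current bond as reference
                        sx, sy, sz = dx, dy, dz
                        dot = dx * sx + dy * sy + dz * sz
                    g = diff / (2.0 * (inv_mass[a] + inv_mass[b]) * dot)
                    ax = g * inv_mass[a]
                    bx = g * inv_mass[b]
                    pos_new[a, 0] -= ax * sx
                    pos_new[a, 1] -= ax * sy
                    pos_new[a, 2] -= ax * sz
                    pos_new[b, 0] += bx * sx
                    pos_new[b, 1] += bx * sy
                    pos_new[b, 2] += bx * sz
                    if dt > 0.0:
                        vel[a, 0] -= ax * sx / dt
                        vel[a, 1] -= ax * sy / dt
                        vel[a, 2] -= ax * sz / dt
                        vel[b, 0] += bx * sx / dt
                        vel[b, 1] += bx * sy / dt
                        vel[b, 2] += bx * sz / dt
            if done:
                converged = True
                break
        if not converged:
            n_fail += 1
    return n_fail


@njit(cache=True)
def rattle_velocities(pos, vel, inv_mass, water_start, tol, max_iter):
    """RATTLE velocity projection: remove bond-directed relative velocity."""
    n_fail = 0
    for w in range(water_start.shape[0]):
        o = water_start[w]
        converged = False
        for _ in range(max_iter):
            done = True
            for c in range(3):
                if c == 0:
                    a, b = o, o + 1
                elif c == 1:
                    a, b = o, o + 2
                else:
                    a, b = o + 1, o + 2
                rx = pos[a, 0] - pos[b, 0]
                ry = pos[a, 1] - pos[b, 1]
                rz = pos[a, 2] - pos[b, 2]
                vx = vel[a, 0] - vel[b, 0]
                vy = vel[a, 1] - vel[b, 1]
                vz = vel[a, 2] - vel[b, 2]
                rv = rx * vx + ry * vy + rz * vz
                r2 = rx * rx + ry * ry + rz * rz
                if abs(rv) > tol * r2:
                    done = False
                    k = rv / ((inv_mass[a] + inv_mass[b]) * r2)
                    vel[a, 0] -= k * inv_mass[a] * rx
                    vel[a, 1] -= k * inv_mass[a] * ry
                    vel[a, 2] -= k * inv_mass[a] * rz
                    vel[b, 0] += k * inv_mass[b] * rx
                    vel[b, 1] += k * inv_mass[b] * ry
                    vel[b, 2] += k * inv_mass[b] * rz
            if done:
                converged = True
                break
        if not converged:
            n_fail += 1
    return n_fail


def constrain_water(pos: np.ndarray, masses: np.ndarray, d_oh: float = 1.0, d_hh: float | None = None):
    """Restore a near-rigid (O, H, H) triplet to exact rigid geometry.

    Positions are a (3, 3) array ordered O, H, H; the correction conserves
    linear momentum (constraint impulses are internal and mass-weighted).
    Raises :class:`ConstraintError` on degenerate (collinear) geometry or
    non-convergence.
    """
    if d_hh is None:
        d_hh = 2.0 * d_oh * math.sin(math.radians(109.47) / 2.0)
    pos = np.array(pos, dtype=float)
    b1 = pos[1] - pos[0]
    b2 = pos[2] - pos[0]
    if np.linalg.norm(np.cross(b1, b2)) < 1.0e-8:
        raise ConstraintError("degenerate collinear water geometry")
    vel = np.zeros_like(pos)
    inv_mass = 1.0 / np.asarray(masses, dtype=float)
    start = np.array([0], dtype=np.int64)
    n_fail = shake_positions(pos, pos.copy(), vel, inv_mass, start, d_oh, d_hh, 0.0, SHAKE_TOL, SHAKE_MAX_ITER)
    if n_fail:
        raise ConstraintError("water constraint iteration did not converge")
    return pos


def water_start_indices(species: list[str], mol_id: np.ndarray) -> np.ndarray:
    """Indices of the O site of each rigid (O, H, H) water triplet."""
    starts = []
    n = len(species)
    for i, s in enumerate(species):
        if s == "O" and i + 2 < n and species[i + 1] == "H" and species[i + 2] == "H":
            if mol_id[i] == mol_id[i + 1] == mol_id[i + 2]:
                starts.append(i)
    return np.asarray(starts, dtype=np.int64)
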