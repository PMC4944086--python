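"""Total energies and forces for a configuration.

Aggregates the three interaction terms — pairwise LJ + Coulomb among
mobile sites, Coulomb between mobile sites and the frozen wall charges,
and the Steele wall term — with analytic forces.  The inner pair loops
are numba-compiled; Lorentz-Berthelot mixing is applied inline from the
pure per-species parameters.

Periodic wrapping is along z only (the pore axis).  Two Coulomb modes are
available for dynamics: ``bare`` (full minimum-image 1/r, for small test
systems and the implicit-solvent mode) and ``cutoff_rf`` (reaction-field
damped cutoff, the fast explicit-solvent mode).  A lattice-summed Ewald
route is available through :func:`electrostatic_energy` for validation
and small systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import COULOMB_KJ
from .electrostatics import CutoffError, ewald_energy_forces
from .forcefield import ForceField
from .system import SystemConfiguration

__all__ = [
    "OverlapError",
    "ParticleArrays",
    "total_energy_forces",
    "electrostatic_energy",
]

OVERLAP_R = 0.1  # Å; closer non-bonded centers abort the evaluation


class OverlapError(RuntimeError):
    """Two non-bonded centers closer than the overlap threshold."""


@dataclass
class ParticleArrays:
    """Flat per-particle parameter arrays consumed by the kernels."""

    sigma: np.ndarray  # pure LJ sigma per particle (0 for LJ-inactive)
    epsilon: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    mol_id: np.ndarray
    steele_a: np.ndarray  # 2 pi rho eps_wf sigma_wf^2 Delta, per particle
    steele_s: np.ndarray  # sigma_wf per particle
    steele_delta: float  # wall interlayer spacing, Å
    wall_pos: np.ndarray
    wall_q: np.ndarray

    @classmethod
    def from_config(cls, config: SystemConfiguration) -> "ParticleArrays":
        ff = config.forcefield
        import dataclasses as _dc

        wall = _dc.replace(ff.wall, r_n=config.geometry.r_n)
        n = config.n_particles
        sigma = np.zeros(n)
        epsilon = np.zeros(n)
        steele_a = np.zeros(n)
        steele_s = np.zeros(n)
        for i, name in enumerate(config.species):
            sp = ff[name]
            sigma[i] = sp.sigma
            epsilon[i] = sp.epsilon
            if sp.lj_active:
                steele_a[i] = wall.prefactor(sp)
                steele_s[i] = wall.sigma_wf(sp)
        return cls(
            sigma=sigma,
            epsilon=epsilon,
            charge=config.charges,
            mass=config.masses,
            mol_id=config.mol_id.astype(np.int64),
            steele_a=steele_a,
            steele_s=steele_s,
            steele_delta=wall.delta,
            wall_pos=config.wall_positions,
            wall_q=config.wall_charges,
        )


@njit(cache=True)
def _pair_kernel(pos, q, sig, eps, mol, l_z, use_pbc, rc2, use_rf, eps_r):
    """LJ + Coulomb over distinct mobile pairs; returns (E, F, min_r2)."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    min_r2 = 1.0e30
    ke = COULOMB_KJ / eps_r
    krf = 0.0
    crf = 0.0
    if use_rf:
        krf = 0.5 / (rc2 * np.sqrt(rc2))
        crf = 1.5 / np.sqrt(rc2)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol[i] == mol[j] and mol[i] >= 0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if use_pbc:
                dz -= l_z * np.floor(dz / l_z + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            if use_rf and r2 > rc2:
                continue
            if r2 < min_r2:
                min_r2 = r2
            r = np.sqrt(r2)
            mag = 0.0
            qq = q[i] * q[j]
            if qq != 0.0:
                if use_rf:
                    e += ke * qq * (1.0 / r + krf * r2 - crf)
                    mag += ke * qq * (1.0 / (r2 * r) - 2.0 * krf)
                else:
                    e += ke * qq / r
                    mag += ke * qq / (r2 * r)
            eij = np.sqrt(eps[i] * eps[j])
            if eij > 0.0:
                sij = 0.5 * (sig[i] + sig[j])
                sr6 = (sij * sij / r2) ** 3
                u = 4.0 * eij * (sr6 * sr6 - sr6)
                if use_rf:
                    sr6c = (sij * sij / rc2) ** 3
                    u -= 4.0 * eij * (sr6c * sr6c - sr6c)
                e += u
                mag += 24.0 * eij * (2.0 * sr6 * sr6 - sr6) / r2
            f[i, 0] += mag * dx
            f[i, 1] += mag * dy
            f[i, 2] += mag * dz
            f[j, 0] -= mag * dx
            f[j, 1] -= mag * dy
            f[j, 2] -= mag * dz
    return e, f, min_r2


@njit(cache=True)
def _wall_coulomb_kernel(pos, q, wpos, wq, l_z, use_pbc, rc2, use_rf, eps_r):
    """Coulomb between mobile charges and frozen wall sites."""
    n = pos.shape[0]
    m = wpos.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    ke = COULOMB_KJ / eps_r
    krf = 0.0
    crf = 0.0
    if use_rf:
        krf = 0.5 / (rc2 * np.sqrt(rc2))
        crf = 1.5 / np.sqrt(rc2)
    for i in range(n):
        if q[i] == 0.0:
            continue
        for j in range(m):
            dx = pos[i, 0] - wpos[j, 0]
            dy = pos[i, 1] - wpos[j, 1]
            dz = pos[i, 2] - wpos[j, 2]
            if use_pbc:
                dz -= l_z * np.floor(dz / l_z + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            if use_rf and r2 > rc2:
                continue
            r = np.sqrt(r2)
            qq = q[i] * wq[j]
            if use_rf:
                e += ke * qq * (1.0 / r + krf * r2 - crf)
                mag = ke * qq * (1.0 / (r2 * r) - 2.0 * krf)
            else:
                e += ke * qq / r
                mag = ke * qq / (r2 * r)
            f[i, 0] += mag * dx
            f[i, 1] += mag * dy
            f[i, 2] += mag * dz
    return e, f


def steele_energy_forces(pos: np.ndarray, arrays: ParticleArrays, r_n: float):
    """Steele wall term for every LJ-active particle (vectorized).

    Raises ValueError if any Steele-active particle sits at or outside the
    wall.
    """
    n = len(pos)
    f = np.zeros((n, 3))
    active = arrays.steele_a > 0
    if not np.any(active):
        return 0.0, f
    x, y = pos[active, 0], pos[active, 1]
    r = np.hypot(x, y)
    if np.any(r >= r_n):
        raise ValueError("particle at or outside the pore wall")
    z = r_n - r
    a = arrays.steele_a[active]
    s = arrays.steele_s[active]
    delta = arrays.steele_delta
    sz = s / z
    zc = z + 0.61 * delta
    u = a * (0.4 * sz**10 - sz**4 - s**4 / (3.0 * delta * zc**3))
    du_dz = a * (-4.0 * sz**10 / z + 4.0 * sz**4 / z + s**4 / (delta * zc**4))
    # radial force -dU/dr = +dU/dz, directed along the radial unit vector
    with np.errstate(invalid="ignore"):
        inv_r = np.where(r > 0, 1.0 / r, 0.0)
    fr = du_dz
    fa = np.zeros((active.sum(), 3))
    fa[:, 0] = fr * x * inv_r
    fa[:, 1] = fr * y * inv_r
    f[active] = fa
    return float(u.sum()), f


def total_energy_forces(
    config: SystemConfiguration,
    coulomb: str = "bare",
    r_cut: float | None = None,
    eps_r: float = 1.0,
    arrays: ParticleArrays | None = None,
    check_overlap: bool = True,
    return_breakdown: bool = False,
):
    """Total potential energy (kJ/mol) and per-particle forces (kJ/(mol Å)).

    Wall-charge sites are frozen: they exert forces on the fluid but
    receive none.  ``coulomb`` selects ``bare`` minimum-image 1/r or the
    ``cutoff_rf`` reaction-field mode (cutoff must not exceed half the
    periodic length).
    """
    arrays = arrays or ParticleArrays.from_config(config)
    pos = config.positions
    geo = config.geometry
    n = len(pos)
    if n == 0:
        out = (0.0, np.zeros((0, 3)))
        return out + ({"lj+coulomb": 0.0, "wall_coulomb": 0.0, "steele": 0.0},) if return_breakdown else out
    use_rf = coulomb == "cutoff_rf"
    if use_rf:
        if r_cut is None:
            r_cut = min(10.0, 0.5 * geo.l_z)
        if r_cut > 0.5 * geo.l_z:
            raise CutoffError(f"cutoff {r_cut} exceeds half the periodic length {geo.l_z}")
        rc2 = r_cut * r_cut
    else:
        rc2 = 0.0

    e_pair, f_pair, min_r2 = _pair_kernel(
        pos, arrays.charge, arrays.sigma, arrays.epsilon, arrays.mol_id,
        geo.l_z, True, rc2, use_rf, eps_r,
    )
    if check_overlap and min_r2 < OVERLAP_R * OVERLAP_R:
        raise OverlapError(f"non-bonded centers closer than {OVERLAP_R} Å")
    e_wall, f_wall = _wall_coulomb_kernel(
        pos, arrays.charge, arrays.wall_pos, arrays.wall_q,
        geo.l_z, True, rc2, use_rf, eps_r,
    )
    e_st, f_st = steele_energy_forces(pos, arrays, geo.r_n)
    e = e_pair + e_wall + e_st
    f = f_pair + f_wall + f_st
    if return_breakdown:
        return e, f, {"lj+coulomb": e_pair, "wall_coulomb": e_wall, "steele": e_st}
    return e, f


def electrostatic_energy(config: SystemConfiguration, method: str = "ewald", r_cut: float | None = None):
    """Total Coulomb energy of mobile plus frozen wall charges.

    ``ewald`` embeds the quasi-1D pore in an orthorhombic cell with
    lateral vacuum padding (box 4 r_n x 4 r_n x l_z) and requires a
    neutral system; ``cutoff_rf`` is the damped-cutoff fast mode.
    """
    geo = config.geometry
    pos = np.vstack([config.positions, config.wall_positions])
    q = np.concatenate([config.charges, config.wall_charges])
    mol = np.concatenate([config.mol_id, np.full(config.n_wall_charges, -1, dtype=np.int64)])
    if method == "ewald":
        box = (4.0 * geo.r_n, 4.0 * geo.r_n, geo.l_z)
        e, _ = ewald_energy_forces(pos, q, box, mol_id=mol)
        return e
    if method == "cutoff_rf":
        if r_cut is None:
            r_cut = min(10.0, 0.5 * geo.l_z)
        from .electrostatics import coulomb_cutoff_rf

        return coulomb_cutoff_rf(pos, q, r_cut, l_z=geo.l_z, mol_id=mol)
    raise ValueError(f"unknown electrostatics method: {method!r}")
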