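"""Implicit-solvent (primitive-model) Metropolis Monte Carlo.

Water is replaced by a uniform dielectric continuum (eps_r = 78.4) and the
ions keep their LJ parameters, the Steele wall term, and Coulomb coupling
to the frozen wall charges, all scaled by 1/eps_r where electrostatic.
Single-particle displacement moves with the standard Metropolis
acceptance obey detailed balance, so long runs sample the Boltzmann
distribution of the reduced model.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import COULOMB_KJ

__all__ = ["metropolis_accept", "mc_sweep_chunk", "mc_total_energy"]

# reject outright when the trial radius leaves less than this wall gap (the
# Steele term diverges there anyway)
MIN_WALL_GAP = 0.2


def metropolis_accept(delta_u: float, beta: float, u: float) -> bool:
    """The Metropolis rule: accept if du <= 0, else if u < exp(-beta du).

    ``u`` is a uniform(0,1) variate supplied by the caller so the rule is a
    pure function.
    """
    if delta_u <= 0.0:
        return True
    return u < math.exp(-beta * delta_u)


@njit(cache=True)
def _particle_energy(i, x, y, z, pos, q, sig, eps, sa, ss, delta, wpos, wq, r_n, l_z, inv_eps_r):
    """Interaction energy of particle i at a trial position with all others."""
    n = pos.shape[0]
    e = 0.0
    ke = COULOMB_KJ * inv_eps_r
    for j in range(n):
        if j == i:
            continue
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        dz = z - pos[j, 2]
        dz -= l_z * np.floor(dz / l_z + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        qq = q[i] * q[j]
        if qq != 0.0:
            e += ke * qq / r
        eij = np.sqrt(eps[i] * eps[j])
        if eij > 0.0:
            sij = 0.5 * (sig[i] + sig[j])
            sr6 = (sij * sij / r2) ** 3
            e += 4.0 * eij * (sr6 * sr6 - sr6)
    for j in range(wpos.shape[0]):
        qq = q[i] * wq[j]
        if qq != 0.0:
            dx = x - wpos[j, 0]
            dy = y - wpos[j, 1]
            dz = z - wpos[j, 2]
            dz -= l_z * np.floor(dz / l_z + 0.5)
            e += ke * qq / np.sqrt(dx * dx + dy * dy + dz * dz)
    if sa[i] > 0.0:
        rr = np.sqrt(x * x + y * y)
        zz = r_n - rr
        s = ss[i]
        sz = s / zz
        zc = zz + 0.61 * delta
        e += sa[i] * (0.4 * sz**10 - sz**4 - s**4 / (3.0 * delta * zc**3))
    return e


@njit(cache=True)
def mc_total_energy(pos, q, sig, eps, sa, ss, delta, wpos, wq, r_n, l_z, inv_eps_r):
    """Total primitive-model energy (kJ/mol); half the pairwise double count."""
    n = pos.shape[0]
    e_pair = 0.0
    for i in range(n):
        e_pair += _particle_energy(
            i, pos[i, 0], pos[i, 1], pos[i, 2],
            pos, q, sig, eps,
            np.zeros_like(sa), ss, delta,
            wpos[:0], wq[:0], r_n, l_z, inv_eps_r,
        )
    e = 0.5 * e_pair
    # one-body terms counted once
    ke = COULOMB_KJ * inv_eps_r
    for i in range(n):
        for j in range(wpos.shape[0]):
            qq = q[i] * wq[j]
            if qq != 0.0:
                dx = pos[i, 0] - wpos[j, 0]
                dy = pos[i, 1] - wpos[j, 1]
                dz = pos[i, 2] - wpos[j, 2]
                dz -= l_z * np.floor(dz / l_z + 0.5)
                e += ke * qq / np.sqrt(dx * dx + dy * dy + dz * dz)
        if sa[i] > 0.0:
            rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2)
            zz = r_n - rr
            s = ss[i]
            sz = s / zz
            zc = zz + 0.61 * delta
            e += sa[i] * (0.4 * sz**10 - sz**4 - s**4 / (3.0 * delta * zc**3))
    return e


@njit(cache=True)
def mc_sweep_chunk(pos, q, sig, eps, sa, ss, delta, wpos, wq, r_n, l_z, beta, inv_eps_r, step, rand, idx):
    """Run len(idx) Metropolis displacement moves in place; returns accepts.

    ``rand`` is a (n_moves, 4) array of uniform(0,1) variates (three for
    the cubic displacement, one for acceptance) and ``idx`` the particle
    picked for each move, both pre-drawn by the caller's seeded generator
    so the chain is a pure function of its inputs.
    """
    n_acc = 0
    for m in range(idx.shape[0]):
        i = idx[m]
        xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
        xn = xo + step * (rand[m, 0] - 0.5)
        yn = yo + step * (rand[m, 1] - 0.5)
        zn = zo + step * (rand[m, 2] - 0.5)
        zn -= l_z * np.floor(zn / l_z)
        if np.sqrt(xn * xn + yn * yn) >= r_n - MIN_WALL_GAP:
            continue
        e_old = _particle_energy(i, xo, yo, zo, pos, q, sig, eps, sa, ss, delta, wpos, wq, r_n, l_z, inv_eps_r)
        e_new = _particle_energy(i, xn, yn, zn, pos, q, sig, eps, sa, ss, delta, wpos, wq, r_n, l_z, inv_eps_r)
        du = e_new - e_old
        if du <= 0.0 or rand[m, 3] < np.exp(-beta * du):
            pos[i, 0] = xn
            pos[i, 1] = yn
            pos[i, 2] = zn
            n_acc += 1
    return n_acc
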