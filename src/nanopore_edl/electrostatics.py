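"""Point-charge electrostatics for the pore geometry.

Three evaluation routes:

* ``coulomb_direct`` — bare 1/r over all pairs with minimum-image wrapping
  along the periodic pore axis; the model definition used by the
  implicit-solvent Monte-Carlo mode and by small-fixture oracles.
* ``coulomb_cutoff_rf`` — cutoff Coulomb with conductor-like reaction-field
  damping (force goes smoothly to zero at the cutoff); the fast mode for
  explicit-solvent dynamics.
* ``ewald_energy_forces`` — standard 3D Ewald split (real + reciprocal +
  self + excluded-pair correction) in an orthorhombic cell.  The quasi-1D
  pore is embedded with lateral vacuum padding.

Energies are kJ/mol for charges in e and lengths in Å.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erfc

from .constants import COULOMB_KJ

__all__ = [
    "coulomb_direct",
    "coulomb_cutoff_rf",
    "ewald_energy_forces",
    "NeutralityError",
    "CutoffError",
]


class NeutralityError(ValueError):
    """Ewald summation requires a net-neutral cell."""


class CutoffError(ValueError):
    """Cutoff exceeds half the minimum periodic dimension."""


def _pair_vectors(pos: np.ndarray, l_z: float | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(pos)
    iu, ju = np.triu_indices(n, k=1)
    d = pos[iu] - pos[ju]
    if l_z is not None:
        d[:, 2] -= l_z * np.round(d[:, 2] / l_z)
    return iu, ju, d


def coulomb_direct(
    pos: np.ndarray,
    q: np.ndarray,
    l_z: float | None = None,
    eps_r: float = 1.0,
    mol_id: np.ndarray | None = None,
    forces: bool = False,
):
    """Bare Coulomb sum over distinct pairs (minimum image along z only).

    Pairs sharing a non-negative ``mol_id`` (sites of one rigid molecule)
    are excluded.  Returns energy, or ``(energy, forces)``.
    """
    pos = np.asarray(pos, dtype=float)
    q = np.asarray(q, dtype=float)
    if len(pos) < 2 or not np.any(q):
        e = 0.0
        return (e, np.zeros_like(pos)) if forces else e
    iu, ju, d = _pair_vectors(pos, l_z)
    keep = np.ones(len(iu), dtype=bool)
    if mol_id is not None:
        mol_id = np.asarray(mol_id)
        same = (mol_id[iu] == mol_id[ju]) & (mol_id[iu] >= 0)
        keep &= ~same
    d = d[keep]
    iu, ju = iu[keep], ju[keep]
    r = np.linalg.norm(d, axis=1)
    k = COULOMB_KJ / eps_r
    qq = q[iu] * q[ju]
    e = float(np.sum(k * qq / r))
    if not forces:
        return e
    f = np.zeros_like(pos)
    fpair = (k * qq / r**3)[:, None] * d
    np.add.at(f, iu, fpair)
    np.add.at(f, ju, -fpair)
    return e, f


def coulomb_cutoff_rf(
    pos: np.ndarray,
    q: np.ndarray,
    r_cut: float,
    l_z: float | None = None,
    eps_r: float = 1.0,
    mol_id: np.ndarray | None = None,
    forces: bool = False,
):
    """Cutoff Coulomb with conductor reaction field.

    u(r) = (k q_i q_j / eps_r) * (1/r + r^2/(2 r_c^3) - 3/(2 r_c)),  r < r_c

    shifted to zero at the cutoff with a force that also vanishes there.
    """
    if l_z is not None and r_cut > 0.5 * l_z:
        raise CutoffError(f"cutoff {r_cut} exceeds half the periodic length {l_z}")
    pos = np.asarray(pos, dtype=float)
    q = np.asarray(q, dtype=float)
    if len(pos) < 2 or not np.any(q):
        e = 0.0
        return (e, np.zeros_like(pos)) if forces else e
    iu, ju, d = _pair_vectors(pos, l_z)
    keep = np.ones(len(iu), dtype=bool)
    if mol_id is not None:
        mol_id = np.asarray(mol_id)
        keep &= ~((mol_id[iu] == mol_id[ju]) & (mol_id[iu] >= 0))
    r = np.linalg.norm(d, axis=1)
    keep &= r < r_cut
    d, r, iu, ju = d[keep], r[keep], iu[keep], ju[keep]
    k = COULOMB_KJ / eps_r
    krf = 0.5 / r_cut**3
    crf = 1.5 / r_cut
    qq = k * q[iu] * q[ju]
    e = float(np.sum(qq * (1.0 / r + krf * r * r - crf)))
    if not forces:
        return e
    f = np.zeros_like(pos)
    mag = qq * (1.0 / r**3 - 2.0 * krf)  # -(dU/dr)/r
    fpair = mag[:, None] * d
    np.add.at(f, iu, fpair)
    np.add.at(f, ju, -fpair)
    return e, f


def ewald_energy_forces(
    pos: np.ndarray,
    q: np.ndarray,
    box: tuple[float, float, float],
    mol_id: np.ndarray | None = None,
    alpha: float | None = None,
    accuracy: float = 1.0e-8,
    forces: bool = True,
):
    """3D Ewald energy (and forces) for point charges in an orthorhombic box.

    The splitting parameter defaults to ``alpha = 3.5 / r_max`` with
    ``r_max = min(box)/2`` so a single minimum image suffices in real
    space; the reciprocal sum is truncated where the Gaussian weight drops
    below ``accuracy``.  Sites sharing a non-negative ``mol_id`` have
    their direct interaction removed (rigid-molecule exclusion).

    Raises :class:`NeutralityError` for a non-neutral cell (tin-foil
    boundary conditions assume neutrality).
    """
    pos = np.asarray(pos, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    if abs(q.sum()) > 1.0e-9:
        raise NeutralityError(f"net charge {q.sum():g} e; Ewald cell must be neutral")
    n = len(pos)
    vol = float(np.prod(box))
    r_max = 0.5 * float(box.min())
    if alpha is None:
        alpha = 3.5 / r_max
    f = np.zeros_like(pos)

    # real space, single minimum image in all three dimensions
    iu, ju = np.triu_indices(n, k=1)
    d = pos[iu] - pos[ju]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    within = r < r_max
    same_mol = np.zeros(len(iu), dtype=bool)
    if mol_id is not None:
        mol_id = np.asarray(mol_id)
        same_mol = (mol_id[iu] == mol_id[ju]) & (mol_id[iu] >= 0)
    sel = within & ~same_mol
    qq = q[iu] * q[ju]
    rr = r[sel]
    e_real = float(np.sum(qq[sel] * erfc(alpha * rr) / rr))
    if forces and rr.size:
        mag = qq[sel] * (
            erfc(alpha * rr) / rr**2 + 2.0 * alpha / math.sqrt(math.pi) * np.exp(-((alpha * rr) ** 2)) / rr
        ) / rr
        fpair = mag[:, None] * d[sel]
        np.add.at(f, iu[sel], fpair)
        np.add.at(f, ju[sel], -fpair)

    # excluded intramolecular pairs: remove the full 1/r interaction that
    # the reciprocal sum implicitly includes -> subtract erf(a r)/r term
    e_excl = 0.0
    if np.any(same_mol):
        re = r[same_mol]
        qqe = qq[same_mol]
        from scipy.special import erf

        e_excl = -float(np.sum(qqe * erf(alpha * re) / re))
        if forces:
            mag = -qqe * (
                erf(alpha * re) / re**2 - 2.0 * alpha / math.sqrt(math.pi) * np.exp(-((alpha * re) ** 2)) / re
            ) / re
            fpair = mag[:, None] * d[same_mol]
            np.add.at(f, iu[same_mol], fpair)
            np.add.at(f, ju[same_mol], -fpair)

    # reciprocal space
    k_cut = 2.0 * alpha * math.sqrt(-math.log(accuracy))
    nmax = np.ceil(k_cut * box / (2.0 * math.pi)).astype(int)
    gx = np.arange(-nmax[0], nmax[0] + 1)
    gy = np.arange(-nmax[1], nmax[1] + 1)
    gz = np.arange(-nmax[2], nmax[2] + 1)
    gg = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    gg = gg[np.any(gg != 0, axis=1)]
    kvec = 2.0 * math.pi * gg / box
    k2 = np.sum(kvec**2, axis=1)
    keep = k2 <= k_cut**2
    kvec, k2 = kvec[keep], k2[keep]
    phase = pos @ kvec.T  # (n, nk)
    cosp, sinp = np.cos(phase), np.sin(phase)
    re_s = q @ cosp
    im_s = q @ sinp
    w = np.exp(-k2 / (4.0 * alpha**2)) / k2
    e_recip = (2.0 * math.pi / vol) * float(np.sum(w * (re_s**2 + im_s**2)))
    if forces:
        # F_i = k_e * (4 pi / V) q_i sum_k w k [sin(k.r_i) Re S - cos(k.r_i) Im S]
        coef = sinp * re_s[None, :] - cosp * im_s[None, :]  # (n, nk)
        f += (4.0 * math.pi / vol) * q[:, None] * ((coef * w[None, :]) @ kvec)

    e_self = -alpha / math.sqrt(math.pi) * float(np.sum(q**2))

    e = COULOMB_KJ * (e_real + e_excl + e_recip + e_self)
    if forces:
        return e, COULOMB_KJ * f
    return e
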