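"""Interaction model: Lennard-Jones pairs, the Steele 10-4-3 wall, and the
rigid three-site water model.

Mobile species interact pairwise through LJ + Coulomb terms with
Lorentz-Berthelot mixing; the pore wall acts on every LJ-active species
through the structureless Steele potential, a one-dimensional function of
the distance to the cylindrical wall obtained by integrating the LJ
interaction of a layered solid.  Frozen wall charges couple to the fluid
through Coulomb's law only.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import KB

__all__ = [
    "SpeciesParams",
    "PairParams",
    "WaterModel",
    "WallModel",
    "ForceField",
    "combine_lorentz_berthelot",
    "lj_energy",
    "lj_energy_force",
    "load_forcefield",
    "default_forcefield",
]


class ParameterError(ValueError):
    """Invalid force-field parameter."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species mass, charge and pure-pair LJ parameters.

    ``sigma`` (Å) and ``epsilon`` (kJ/mol) describe the like-pair LJ
    interaction; species with ``epsilon == 0`` (hydrogen, wall charges)
    carry no LJ term at all.
    """

    name: str
    mass: float  # g/mol
    charge: float  # e
    sigma: float  # Å
    epsilon: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ParameterError(f"{self.name}: negative epsilon {self.epsilon}")
        if self.sigma < 0:
            raise ParameterError(f"{self.name}: negative sigma {self.sigma}")
        if self.mass < 0:
            raise ParameterError(f"{self.name}: negative mass {self.mass}")
        if self.lj_active and self.sigma == 0:
            raise ParameterError(f"{self.name}: LJ-active species needs sigma > 0")

    @property
    def lj_active(self) -> bool:
        return self.epsilon > 0


@dataclass(frozen=True)
class PairParams:
    """Mixed-pair LJ parameters."""

    sigma_ij: float  # Å
    epsilon_ij: float  # kJ/mol


def combine_lorentz_berthelot(a: SpeciesParams, b: SpeciesParams) -> PairParams:
    """Lorentz-Berthelot mixing: arithmetic-mean sigma, geometric-mean epsilon."""
    if a.epsilon < 0 or b.epsilon < 0:
        raise ParameterError("negative epsilon in combining rule")
    return PairParams(
        sigma_ij=0.5 * (a.sigma + b.sigma),
        epsilon_ij=math.sqrt(a.epsilon * b.epsilon),
    )


def lj_energy(r, sigma: float, epsilon: float):
    """12-6 Lennard-Jones energy ``4*eps*((s/r)^12 - (s/r)^6)`` in kJ/mol.

    ``r`` may be a scalar or array of separations in Å; all entries must be
    positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ energy undefined for r <= 0")
    sr6 = (sigma / r) ** 6
    out = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return out if out.ndim else float(out)


def lj_energy_force(r, sigma: float, epsilon: float):
    """LJ energy and the radial force ``-dU/dr`` (kJ/(mol·Å))."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ energy undefined for r <= 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6 * sr6 - sr6)
    # -dU/dr = 24 eps (2 (s/r)^12 - (s/r)^6) / r
    f = 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r
    if u.ndim:
        return u, f
    return float(u), float(f)


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site SPC/E water: one LJ oxygen, three point charges.

    The molecule is kept rigid during dynamics by distance constraints on
    the two O-H bonds and the H-H separation.
    """

    q_o: float = -0.8476  # e
    q_h: float = 0.4238  # e
    r_oh: float = 1.0  # Å
    angle_hoh: float = 109.47  # degrees

    def __post_init__(self) -> None:
        if abs(self.q_o + 2.0 * self.q_h) > 1e-12:
            raise ParameterError("water molecule must be net neutral")

    @property
    def r_hh(self) -> float:
        """H-H distance implied by the rigid geometry (Å)."""
        return 2.0 * self.r_oh * math.sin(math.radians(self.angle_hoh) / 2.0)


@dataclass(frozen=True)
class WallModel:
    """Steele 10-4-3 wall of a cylindrical pore of radius ``r_n``.

    u_wf(r) = 2 pi rho_w eps_wf sigma_wf^2 Delta *
              [ (2/5)(sigma_wf/z)^10 - (sigma_wf/z)^4
                - sigma_wf^4 / (3 Delta (z + 0.61 Delta)^3) ],   z = r_n - r

    with the wall-fluid parameters obtained by Lorentz-Berthelot mixing of
    the bulk-solid values (sigma_w, eps_w) with the fluid species.  The
    potential depends on position only through the wall distance z, so the
    same form serves any pore radius.
    """

    r_n: float = 30.0  # Å, pore radius
    delta: float = 2.709  # Å, solid interlayer spacing
    rho_w: float = 42.76  # nm^-3, solid site density
    sigma_w: float = 3.0  # Å
    epsilon_w_over_kb: float = 230.0  # K

    def __post_init__(self) -> None:
        for field in ("r_n", "delta", "rho_w", "sigma_w", "epsilon_w_over_kb"):
            if getattr(self, field) <= 0:
                raise ParameterError(f"wall constant {field} must be positive")

    @property
    def epsilon_w(self) -> float:
        """Wall well depth in kJ/mol."""
        return self.epsilon_w_over_kb * KB

    @property
    def rho_w_a3(self) -> float:
        """Wall site density in Å^-3."""
        return self.rho_w * 1.0e-3

    def sigma_wf(self, species: SpeciesParams) -> float:
        return 0.5 * (self.sigma_w + species.sigma)

    def epsilon_wf(self, species: SpeciesParams) -> float:
        return math.sqrt(self.epsilon_w * species.epsilon)

    def prefactor(self, species: SpeciesParams) -> float:
        """2 pi rho_w eps_wf sigma_wf^2 Delta (kJ/mol)."""
        s = self.sigma_wf(species)
        return 2.0 * math.pi * self.rho_w_a3 * self.epsilon_wf(species) * s * s * self.delta

    def steele_energy(self, r, species: SpeciesParams):
        """Wall energy (kJ/mol) at radial coordinate(s) ``r`` from the axis.

        Requires ``0 <= r < r_n``; diverges repulsively as r -> r_n.
        """
        u, _ = self.steele_energy_force(r, species)
        return u

    def steele_energy_force(self, r, species: SpeciesParams):
        """Energy and radial force ``-dU/dr`` at radial coordinate(s) r.

        The force is negative (axis-ward) in the repulsive region near the
        wall and positive (wall-ward) in the attractive tail.
        """
        r = np.asarray(r, dtype=float)
        if np.any(r < 0) or np.any(r >= self.r_n):
            raise ValueError("Steele potential requires 0 <= r < r_n")
        if not species.lj_active:
            z = np.zeros_like(r)
            if z.ndim:
                return z, z.copy()
            return 0.0, 0.0
        z = self.r_n - r
        s = self.sigma_wf(species)
        a = self.prefactor(species)
        sz = s / z
        zc = z + 0.61 * self.delta
        u = a * (0.4 * sz**10 - sz**4 - s**4 / (3.0 * self.delta * zc**3))
        # dU/dz, then force along r is -dU/dr = +dU/dz
        du_dz = a * (
            -4.0 * sz**10 / z
            + 4.0 * sz**4 / z
            + s**4 / (self.delta * zc**4)
        )
        f_r = du_dz  # dz/dr = -1  =>  -dU/dr = dU/dz
        if u.ndim:
            return u, f_r
        return float(u), float(f_r)

    def planar_1043_energy(self, z, species: SpeciesParams):
        """Classic planar 10-4-3 form at wall distance z (the r_n -> inf limit)."""
        z = np.asarray(z, dtype=float)
        if np.any(z <= 0):
            raise ValueError("wall distance must be positive")
        s = self.sigma_wf(species)
        a = self.prefactor(species)
        sz = s / z
        out = a * (0.4 * sz**10 - sz**4 - s**4 / (3.0 * self.delta * (z + 0.61 * self.delta) ** 3))
        return out if out.ndim else float(out)


class ForceField:
    """Species table + water model + wall constants, with pair lookups."""

    def __init__(self, species: dict[str, SpeciesParams], water: WaterModel, wall: WallModel):
        self.species = dict(species)
        self.water = water
        self.wall = wall
        # stable integer codes for array-based engines
        self.names = list(self.species)
        self.codes = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> SpeciesParams:
        return self.species[name]

    def pair(self, a: str, b: str) -> PairParams:
        return combine_lorentz_berthelot(self.species[a], self.species[b])

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(sigma_ij, epsilon_ij) matrices indexed by species code.

        Pairs involving an LJ-inactive species get epsilon 0 (no LJ term).
        """
        n = len(self.names)
        sig = np.zeros((n, n))
        eps = np.zeros((n, n))
        for i, a in enumerate(self.names):
            for j, b in enumerate(self.names):
                sa, sb = self.species[a], self.species[b]
                if sa.lj_active and sb.lj_active:
                    p = combine_lorentz_berthelot(sa, sb)
                    sig[i, j] = p.sigma_ij
                    eps[i, j] = p.epsilon_ij
        return sig, eps

    def charge_of(self, name: str) -> float:
        return self.species[name].charge

    def mass_of(self, name: str) -> float:
        return self.species[name].mass


def _parse_ini(text: str, source: str) -> ForceField:
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    cp.read_string(text, source=source)
    species: dict[str, SpeciesParams] = {}
    for sec in cp.sections():
        if sec.startswith("species."):
            name = sec.split(".", 1)[1]
            s = cp[sec]
            species[name] = SpeciesParams(
                name=name,
                mass=s.getfloat("mass"),
                charge=s.getfloat("charge"),
                sigma=s.getfloat("sigma"),
                epsilon=s.getfloat("epsilon"),
            )
    if "water" in cp:
        w = cp["water"]
        water = WaterModel(
            q_o=species["O"].charge,
            q_h=species["H"].charge,
            r_oh=w.getfloat("r_oh"),
            angle_hoh=w.getfloat("angle_hoh"),
        )
    else:
        water = WaterModel()
    if "wall" in cp:
        wl = cp["wall"]
        wall = WallModel(
            delta=wl.getfloat("delta"),
            rho_w=wl.getfloat("rho_w"),
            sigma_w=wl.getfloat("sigma_w"),
            epsilon_w_over_kb=wl.getfloat("epsilon_w_over_kb"),
        )
    else:
        wall = WallModel()
    required = {"O", "H", "Na+", "Cl-", "WALLQ"}
    missing = required - set(species)
    if missing:
        raise ParameterError(f"parameter file {source} missing species: {sorted(missing)}")
    return ForceField(species, water, wall)


def load_forcefield(path: str | Path) -> ForceField:
    """Load a force field from a plain-text parameter file."""
    path = Path(path)
    return _parse_ini(path.read_text(), str(path))


def default_forcefield() -> ForceField:
    """The packaged default parameter set (silica-like wall, SPC/E water)."""
    text = resources.files("nanopore_edl.data").joinpath("forcefield.ini").read_text()
    return _parse_ini(text, "nanopore_edl/data/forcefield.ini")
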