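"""System containers: pore geometry and particle configurations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import E_CHARGE
from .forcefield import ForceField, default_forcefield

__all__ = ["PoreGeometry", "SystemConfiguration"]


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore, periodic along its axis (z).

    ``r_n`` is the pore radius in Å; ``l_z`` the periodic repeat length.
    The default length puts the standard filling (1045 waters plus ions)
    near liquid water density for the 3 nm-radius pore.
    """

    r_n: float = 30.0
    l_z: float = 14.0

    def __post_init__(self) -> None:
        if self.r_n <= 0 or self.l_z <= 0:
            raise ValueError("pore radius and length must be positive")

    @property
    def volume_a3(self) -> float:
        """Nominal cylinder volume in Å^3."""
        return float(np.pi * self.r_n**2 * self.l_z)

    @property
    def wall_area_m2(self) -> float:
        """Inner wall area in m^2."""
        return float(2.0 * np.pi * (self.r_n * 1e-10) * (self.l_z * 1e-10))

    def wrap_z(self, pos: np.ndarray) -> np.ndarray:
        out = np.array(pos, dtype=float)
        out[..., 2] %= self.l_z
        return out


class SystemConfiguration:
    """Particle coordinates, species tags, velocities and frozen wall charges.

    Mobile sites are grouped into molecules by ``mol_id`` (each rigid water
    shares one id; monatomic ions get unique ids).  Wall charges sit exactly
    on the cylinder r = r_n and are never integrated.
    """

    def __init__(
        self,
        species: list[str],
        positions: np.ndarray,
        velocities: np.ndarray | None,
        mol_id: np.ndarray | None,
        wall_positions: np.ndarray,
        geometry: PoreGeometry,
        forcefield: ForceField | None = None,
        metadata: dict[str, Any] | None = None,
    ):
        self.species = list(species)
        n = len(self.species)
        self.positions = np.asarray(positions, dtype=float).reshape(n, 3)
        self.velocities = (
            np.zeros((n, 3)) if velocities is None else np.asarray(velocities, dtype=float).reshape(n, 3)
        )
        self.mol_id = (
            np.arange(n) if mol_id is None else np.asarray(mol_id, dtype=np.int64).reshape(n)
        )
        self.wall_positions = np.asarray(wall_positions, dtype=float).reshape(-1, 3)
        self.geometry = geometry
        self.forcefield = forcefield or default_forcefield()
        self.metadata = dict(metadata or {})

    # ---- derived arrays -------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.species)

    @property
    def n_wall_charges(self) -> int:
        return len(self.wall_positions)

    @property
    def charges(self) -> np.ndarray:
        ff = self.forcefield
        return np.array([ff.charge_of(s) for s in self.species])

    @property
    def masses(self) -> np.ndarray:
        ff = self.forcefield
        return np.array([ff.mass_of(s) for s in self.species])

    @property
    def wall_charges(self) -> np.ndarray:
        return np.full(self.n_wall_charges, self.forcefield.charge_of("WALLQ"))

    @property
    def total_charge(self) -> float:
        """Net charge of mobile sites plus wall charges, in e."""
        return float(self.charges.sum() + self.wall_charges.sum())

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    @property
    def sigma_s(self) -> float:
        """Magnitude of the wall surface charge density, C/m^2."""
        return abs(float(self.wall_charges.sum())) * E_CHARGE / self.geometry.wall_area_m2

    def count(self, name: str) -> int:
        return self.species.count(name)

    def copy(self) -> "SystemConfiguration":
        return SystemConfiguration(
            species=list(self.species),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            mol_id=self.mol_id.copy(),
            wall_positions=self.wall_positions.copy(),
            geometry=self.geometry,
            forcefield=self.forcefield,
            metadata=dict(self.metadata),
        )

    def validate(self) -> None:
        """Check the construction invariants; raise ValueError on breach."""
        if abs(self.total_charge) > 1e-9:
            raise ValueError(f"system not electroneutral: net {self.total_charge:g} e")
        if self.n_particles and np.any(self.radii >= self.geometry.r_n):
            raise ValueError("mobile particle at or outside the pore wall")
        if self.n_wall_charges:
            rw = np.hypot(self.wall_positions[:, 0], self.wall_positions[:, 1])
            if not np.allclose(rw, self.geometry.r_n, atol=1e-9):
                raise ValueError("wall charges must lie exactly on r = r_n")
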