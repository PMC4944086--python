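"""Initial-configuration builder: the package's synthetic-data generator.

Builds electroneutral NaCl + water fillings of a charged cylindrical pore:
ion counts follow the nominal molarity through the ion/water ratio,
negative elementary wall charges are spread along z on the cylinder
r = r_n (compensated by extra Na+ counterions), and mobile particles are
placed by rejection sampling with a hard minimum-separation rule.
Velocities are Maxwell-Boltzmann.  Every build is a pure function of its
spec, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, WATER_MOLARITY
from .forcefield import ForceField, default_forcefield
from .system import PoreGeometry, SystemConfiguration

__all__ = [
    "BuildSpec",
    "BuildError",
    "ion_counts",
    "place_wall_charges",
    "build_system",
    "build_fixture",
]


class BuildError(RuntimeError):
    """Packing failed (density too high for the geometry)."""


@dataclass(frozen=True)
class BuildSpec:
    """Recipe for one confined-electrolyte configuration.

    ``concentration`` is the nominal molarity defined through the
    ion-pair / water ratio; the reference series is 0.6, 1.3 and 2.0 M with
    1045 waters.
    """

    concentration: float = 0.6  # mol/L, nominal
    n_water: int = 1045
    n_wall_charges: int = 8
    rng_seed: int = 0
    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    temperature: float = 298.0  # K, for Maxwell-Boltzmann velocities
    # ion counts always follow (concentration, n_water); set False to build
    # the implicit-solvent system (ions only, water as continuum)
    explicit_water: bool = True

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.n_water < 0 or self.n_wall_charges < 0:
            raise ValueError("counts must be non-negative")


def ion_counts(concentration: float, n_water: int, n_wall_charges: int) -> tuple[int, int]:
    """Electroneutral (n_Na, n_Cl) for a nominal molarity.

    The salt-pair count uses the molarity ratio against pure water
    (c / 55.345 per water molecule); each -1 e wall charge is balanced by
    one extra Na+ counterion.
    """
    if concentration < 0 or n_water < 0 or n_wall_charges < 0:
        raise ValueError("inputs must be non-negative")
    n_pairs = int(round(concentration * n_water / WATER_MOLARITY))
    return n_pairs + n_wall_charges, n_pairs


def place_wall_charges(geometry: PoreGeometry, n: int, seed: int = 0) -> np.ndarray:
    """n frozen -1 e sites on the cylinder r = r_n, equally spaced in z.

    Axial positions are deterministic (z_k = (k + 1/2) l_z / n); azimuths
    are drawn from the seeded generator so charges do not line up.
    """
    if n == 0:
        return np.zeros((0, 3))
    rng = np.random.default_rng(seed)
    z = (np.arange(n) + 0.5) * geometry.l_z / n
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack(
        [geometry.r_n * np.cos(theta), geometry.r_n * np.sin(theta), z]
    )


def _mb_velocities(rng: np.random.Generator, masses: np.ndarray, temperature: float) -> np.ndarray:
    """Maxwell-Boltzmann velocities (Å/fs) with the COM drift removed."""
    n = len(masses)
    if n == 0:
        return np.zeros((0, 3))
    # <v_x^2> = kB T / m in kJ/g = 1e-4 Å^2/fs^2
    std = 1.0e-2 * np.sqrt(KB * temperature / masses)
    v = rng.normal(size=(n, 3)) * std[:, None]
    mtot = masses.sum()
    if mtot > 0:
        v -= (masses[:, None] * v).sum(axis=0) / mtot
    return v


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _water_template(ff: ForceField) -> np.ndarray:
    """Site offsets (O, H, H) of one rigid water, O at the origin."""
    w = ff.water
    half = math.radians(w.angle_hoh) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [w.r_oh * math.sin(half), 0.0, w.r_oh * math.cos(half)],
            [-w.r_oh * math.sin(half), 0.0, w.r_oh * math.cos(half)],
        ]
    )


def _place_sites(
    rng: np.random.Generator,
    geometry: PoreGeometry,
    sigmas: list[float],
    names: list[str],
    max_attempts: int = 5000,
) -> np.ndarray:
    """Rejection-sample one center per entry with min separation 0.8*sigma_ij."""
    r_max = geometry.r_n - 1.0
    placed: list[np.ndarray] = []
    placed_sig: list[float] = []
    out = np.zeros((len(sigmas), 3))
    for i, (sig, name) in enumerate(zip(sigmas, names)):
        for _ in range(max_attempts):
            x, y = rng.uniform(-r_max, r_max, size=2)
            if x * x + y * y >= r_max * r_max:
                continue
            z = rng.uniform(0.0, geometry.l_z)
            cand = np.array([x, y, z])
            if placed and sig > 0:
                arr = np.asarray(placed)
                d = arr - cand
                d[:, 2] -= geometry.l_z * np.round(d[:, 2] / geometry.l_z)
                dmin = 0.8 * 0.5 * (np.asarray(placed_sig) + sig)
                if np.any(np.sum(d * d, axis=1) < dmin * dmin):
                    continue
            out[i] = cand
            placed.append(cand)
            placed_sig.append(sig)
            break
        else:
            raise BuildError(
                f"could not place particle {i} ({name}) after {max_attempts} attempts; "
                "density too high for the geometry"
            )
    return out


def build_system(spec: BuildSpec, forcefield: ForceField | None = None) -> SystemConfiguration:
    """Build an electroneutral confined electrolyte from a spec.

    Ions and water oxygens are rejection-sampled inside r < r_n - 1 Å with
    no two LJ centers closer than 0.8 sigma_ij; hydrogens follow their
    oxygen in a random rigid orientation.  Deterministic for a fixed spec.
    """
    ff = forcefield or default_forcefield()
    rng = np.random.default_rng(spec.rng_seed)
    geometry = spec.geometry
    n_na, n_cl = ion_counts(spec.concentration, spec.n_water, spec.n_wall_charges)
    wall = place_wall_charges(geometry, spec.n_wall_charges, spec.rng_seed)

    # centers: ions first (largest spheres pack first), then water oxygens
    n_placed_water = spec.n_water if spec.explicit_water else 0
    center_names = ["Na+"] * n_na + ["Cl-"] * n_cl + ["O"] * n_placed_water
    center_sigma = [ff[n].sigma for n in center_names]
    centers = _place_sites(rng, geometry, center_sigma, center_names)

    species: list[str] = []
    mol_id: list[int] = []
    positions: list[np.ndarray] = []
    template = _water_template(ff)
    mol = 0
    for i, name in enumerate(center_names):
        if name == "O":
            rot = _random_rotation(rng)
            sites = centers[i] + template @ rot.T
            positions.extend(sites)
            species.extend(["O", "H", "H"])
            mol_id.extend([mol] * 3)
        else:
            positions.append(centers[i])
            species.append(name)
            mol_id.append(mol)
        mol += 1

    # z stays unwrapped per molecule (hydrogens follow their oxygen even
    # across the periodic boundary); pair terms use minimum image
    pos = np.asarray(positions).reshape(-1, 3) if positions else np.zeros((0, 3))
    masses = np.array([ff.mass_of(s) for s in species])
    vel = _mb_velocities(rng, masses, spec.temperature)

    config = SystemConfiguration(
        species=species,
        positions=pos,
        velocities=vel,
        mol_id=np.asarray(mol_id, dtype=np.int64) if mol_id else None,
        wall_positions=wall,
        geometry=geometry,
        forcefield=ff,
        metadata={
            "rng_seed": spec.rng_seed,
            "concentration": spec.concentration,
            "n_water": spec.n_water,
            "explicit_water": spec.explicit_water,
            "n_wall_charges": spec.n_wall_charges,
            "temperature": spec.temperature,
        },
    )
    config.metadata["sigma_s"] = config.sigma_s
    config.validate()
    return config


def solvate(
    ions: SystemConfiguration,
    n_water: int,
    rng_seed: int = 0,
    temperature: float = 298.0,
) -> SystemConfiguration:
    """Add rigid waters around an existing (e.g. pre-equilibrated) ion set.

    Supports hierarchical equilibration: relax the slow ionic structure
    with the fast implicit-solvent mode first, then solvate and let
    explicit-water dynamics refine locally.  Ion positions are kept; water
    oxygens are rejection-sampled against them with the usual
    0.8 sigma_ij rule.
    """
    ff = ions.forcefield
    rng = np.random.default_rng(rng_seed)
    geometry = ions.geometry
    r_max = geometry.r_n - 1.0
    sig_o = ff["O"].sigma
    placed = [p for p in ions.positions]
    placed_sig = [ff[s].sigma for s in ions.species]
    o_centers = np.zeros((n_water, 3))
    for i in range(n_water):
        for _ in range(5000):
            x, y = rng.uniform(-r_max, r_max, size=2)
            if x * x + y * y >= r_max * r_max:
                continue
            cand = np.array([x, y, rng.uniform(0.0, geometry.l_z)])
            arr = np.asarray(placed)
            d = arr - cand
            d[:, 2] -= geometry.l_z * np.round(d[:, 2] / geometry.l_z)
            dmin = 0.8 * 0.5 * (np.asarray(placed_sig) + sig_o)
            if np.any(np.sum(d * d, axis=1) < dmin * dmin):
                continue
            o_centers[i] = cand
            placed.append(cand)
            placed_sig.append(sig_o)
            break
        else:
            raise BuildError(f"could not place water {i} (O) during solvation")
    species = list(ions.species)
    mol_id = list(ions.mol_id)
    positions = [p for p in ions.positions]
    template = _water_template(ff)
    mol = int(max(mol_id, default=-1)) + 1
    for c in o_centers:
        rot = _random_rotation(rng)
        positions.extend(c + template @ rot.T)
        species.extend(["O", "H", "H"])
        mol_id.extend([mol] * 3)
        mol += 1
    masses = np.array([ff.mass_of(s) for s in species])
    vel = _mb_velocities(rng, masses, temperature)
    out = SystemConfiguration(
        species=species,
        positions=np.asarray(positions),
        velocities=vel,
        mol_id=np.asarray(mol_id, dtype=np.int64),
        wall_positions=ions.wall_positions,
        geometry=geometry,
        forcefield=ff,
        metadata=dict(ions.metadata, solvated=True, n_water=n_water),
    )
    out.validate()
    return out


def build_fixture(kind: str, n: int = 1000, seed: int = 0, geometry: PoreGeometry | None = None) -> SystemConfiguration:
    """Small analytic fixtures for tests and validation runs.

    * ``single_ion`` — one Na+ in an uncharged pore (Boltzmann checks).
    * ``ideal_gas`` — n non-interacting tracers, uniform in the cylinder.
    * ``two_charge`` — a +1/-1 dimer at 3.0 Å in a quasi-infinite pore.
    """
    ff = default_forcefield()
    if kind == "single_ion":
        geo = geometry or PoreGeometry()
        return SystemConfiguration(
            species=["Na+"],
            positions=np.array([[0.5 * geo.r_n, 0.0, 0.5 * geo.l_z]]),
            velocities=None,
            mol_id=None,
            wall_positions=np.zeros((0, 3)),
            geometry=geo,
            forcefield=ff,
            metadata={"fixture": kind},
        )
    if kind == "ideal_gas":
        geo = geometry or PoreGeometry()
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < n:
            xy = rng.uniform(-geo.r_n, geo.r_n, size=(2 * n, 2))
            ok = xy[:, 0] ** 2 + xy[:, 1] ** 2 < geo.r_n**2
            pts.extend(xy[ok])
        xy = np.asarray(pts[:n])
        z = rng.uniform(0.0, geo.l_z, size=n)
        return SystemConfiguration(
            species=["TRACER"] * n,
            positions=np.column_stack([xy, z]),
            velocities=None,
            mol_id=None,
            wall_positions=np.zeros((0, 3)),
            geometry=geo,
            forcefield=ff,
            metadata={"fixture": kind, "rng_seed": seed},
        )
    if kind == "two_charge":
        geo = geometry or PoreGeometry(r_n=200.0, l_z=400.0)
        return SystemConfiguration(
            species=["Na+", "Cl-"],
            positions=np.array([[0.0, 0.0, 0.5 * geo.l_z], [3.0, 0.0, 0.5 * geo.l_z]]),
            velocities=None,
            mol_id=None,
            wall_positions=np.zeros((0, 3)),
            geometry=geo,
            forcefield=ff,
            metadata={"fixture": kind},
        )
    raise ValueError(f"unknown fixture kind: {kind!r}")
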