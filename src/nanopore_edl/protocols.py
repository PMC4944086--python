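"""Composite sampling protocols assembled from the package's stages.

Desk-scale explicit-water runs cannot wait for ions to diffuse to the
wall, so the standard workflow equilibrates hierarchically:

1. implicit-solvent MC at the bulk dielectric (eps_r = 78.4) relaxes the
   overall ionic distribution;
2. a short reduced-dielectric anneal represents the interfacial
   dielectric decrement (water near a charged wall is far less
   polarizable than bulk), letting counterions condense onto the
   discrete wall charges the way they do under full Coulomb coupling;
3. the relaxed ions are solvated with rigid waters and handed to
   explicit MD for local refinement.

Every stage is seeded from the build spec, so the whole protocol is
deterministic.
"""

from __future__ import annotations

from dataclasses import replace

from .builder import BuildSpec, build_system, solvate
from .sampler import RunSpec, run
from .system import SystemConfiguration

__all__ = ["hierarchical_equilibrate"]


def hierarchical_equilibrate(
    spec: BuildSpec,
    mc_moves: int = 200_000,
    anneal_moves: int = 100_000,
    anneal_eps_r: float = 10.0,
) -> SystemConfiguration:
    """Pre-equilibrated, solvated configuration ready for explicit MD.

    ``anneal_eps_r`` is the effective interfacial permittivity of the
    condensation stage; 10 is mid-range for the first water layers at a
    charged oxide surface.  Set ``anneal_moves=0`` to skip the anneal.
    """
    seed = spec.rng_seed
    ions0 = build_system(replace(spec, explicit_water=False))
    mc1 = RunSpec(mode="mc_primitive", n_equil_steps=mc_moves, n_prod_steps=10_000,
                  sample_interval=10_000, rng_seed=seed, t0=spec.temperature)
    stage1 = run(ions0, mc1)
    ions = SystemConfiguration(ions0.species, stage1.frames[-1], None, None,
                               ions0.wall_positions, spec.geometry,
                               ions0.forcefield, ions0.metadata)
    if anneal_moves:
        mc2 = RunSpec(mode="mc_primitive", n_equil_steps=anneal_moves, n_prod_steps=10_000,
                      sample_interval=10_000, rng_seed=seed + 500, t0=spec.temperature,
                      eps_r=anneal_eps_r, mc_step=1.0)
        stage2 = run(ions, mc2)
        ions = SystemConfiguration(ions0.species, stage2.frames[-1], None, None,
                                   ions0.wall_positions, spec.geometry,
                                   ions0.forcefield, ions0.metadata)
    return solvate(ions, spec.n_water, rng_seed=seed, temperature=spec.temperature)
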