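import numpy as np
import pytest

from nanopore_edl.builder import BuildSpec, build_system
from nanopore_edl.forcefield import default_forcefield
from nanopore_edl.sampler import RunSpec, run
from nanopore_edl.system import PoreGeometry


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def small_md_config():
    """A small explicit-water system (fast force/integration tests)."""
    geo = PoreGeometry(r_n=10.0, l_z=20.0)
    spec = BuildSpec(concentration=1.0, n_water=15, n_wall_charges=2, rng_seed=4, geometry=geo)
    return build_system(spec)


@pytest.fixture(scope="session")
def mc_production():
    """A 2 M implicit-solvent production run shared across analysis tests."""
    spec = BuildSpec(concentration=2.0, n_water=1045, n_wall_charges=8, rng_seed=2, explicit_water=False)
    config = build_system(spec)
    rs = RunSpec(
        n_equil_steps=50_000,
        n_prod_steps=500_000,
        sample_interval=1000,
        mode="mc_primitive",
        rng_seed=3,
    )
    return config, run(config, rs)
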