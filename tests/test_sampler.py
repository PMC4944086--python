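"""Sampler tests: integrator accuracy, thermostat, constraints, MC chain."""

import numpy as np
import pytest

from nanopore_edl.builder import BuildSpec, build_fixture, build_system
from nanopore_edl.constants import ACCEL_FACTOR, KB, KINETIC_FACTOR
from nanopore_edl.integrators import (
    ConstraintError,
    berendsen_lambda,
    constrain_water,
    velocity_verlet_step,
)
from nanopore_edl.montecarlo import metropolis_accept
from nanopore_edl.sampler import RunSpec, Trajectory, run
from nanopore_edl.system import PoreGeometry


class TestVelocityVerlet:
    def test_free_streaming(self):
        m = np.array([2.0])
        pos = np.array([[1.0, 2.0, 3.0]])
        vel = np.array([[0.1, -0.2, 0.05]])
        zero = lambda p: np.zeros_like(p)
        p, v, _ = velocity_verlet_step(pos, vel, zero(pos), m, 2.0, zero)
        assert np.allclose(p, pos + 2.0 * vel, atol=1e-15)
        assert np.array_equal(v, vel)

    def test_harmonic_oscillator_against_closed_form(self):
        # omega = sqrt(k/m * accel factor); dt = period/100, 10^4 steps
        k, m = 1.0, np.array([1.0])
        om = np.sqrt(k * ACCEL_FACTOR)
        dt = 0.01 * 2 * np.pi / om
        force = lambda p: -k * p
        p = np.array([[1.0, 0.0, 0.0]])
        v = np.zeros((1, 3))
        f = force(p)
        e0 = 0.5 * k
        xs = np.empty(10_000)
        for i in range(10_000):
            p, v, f = velocity_verlet_step(p, v, f, m, dt, force)
            xs[i] = p[0, 0]
        e_end = 0.5 * k * (p**2).sum() + 0.5 * KINETIC_FACTOR * m[0] * (v**2).sum()
        assert abs(e_end - e0) / e0 < 1e-4  # no secular energy drift
        t = (np.arange(10_000) + 1) * dt
        # matches the analytic cosine over the first period...
        assert np.abs(xs[:100] - np.cos(om * t[:100])).max() < 1e-3
        # ...and the integrator's own closed-form (shifted-frequency) cosine
        # everywhere, to round-off accumulation
        om_d = np.arccos(1 - (om * dt) ** 2 / 2) / dt
        assert np.abs(xs - np.cos(om_d * t)).max() < 1e-9

    def test_time_reversibility(self):
        k, m = 0.7, np.array([1.3])
        force = lambda p: -k * p
        p0 = np.array([[1.0, -0.4, 0.2]])
        v0 = np.array([[0.02, 0.01, -0.03]])
        f0 = force(p0)
        p1, v1, f1 = velocity_verlet_step(p0, v0, f0, m, 5.0, force)
        p2, v2, _ = velocity_verlet_step(p1, v1, f1, m, -5.0, force)
        assert np.abs(p2 - p0).max() < 1e-13
        assert np.abs(v2 - v0).max() < 1e-13


class TestBerendsen:
    def test_identity_at_target(self):
        assert berendsen_lambda(298.0, 298.0, 2.0, 0.1) == 1.0

    def test_continuous_limit(self):
        assert berendsen_lambda(400.0, 298.0, 1e-9, 0.1) == pytest.approx(1.0, abs=1e-9)

    def test_hand_value(self):
        # dt/tau = 0.02, T_inst = 2 T0
        lam = berendsen_lambda(596.0, 298.0, 2.0, 0.1)
        assert lam == pytest.approx(np.sqrt(1 + 0.02 * (0.5 - 1)), rel=1e-12)

    def test_zero_temperature_rejected(self):
        with pytest.raises(ValueError):
            berendsen_lambda(0.0, 298.0, 2.0, 0.1)


class TestWaterConstraints:
    def geometry(self, ff):
        w = ff.water
        half = np.radians(w.angle_hoh) / 2
        return np.array(
            [[0.0, 0.0, 0.0],
             [np.sin(half), 0.0, np.cos(half)],
             [-np.sin(half), 0.0, np.cos(half)]]
        )

    def test_rigid_molecule_unchanged(self, ff):
        pos = self.geometry(ff)
        masses = np.array([15.9994, 1.008, 1.008])
        out = constrain_water(pos, masses)
        assert np.abs(out - pos).max() < 1e-12

    def test_perturbed_molecule_restored(self, ff):
        rng = np.random.default_rng(0)
        masses = np.array([15.9994, 1.008, 1.008])
        w = ff.water
        for _ in range(20):
            pos = self.geometry(ff) * (1 + 0.05 * rng.uniform(-1, 1))
            pos += 0.03 * rng.normal(size=(3, 3))
            com_before = (masses[:, None] * pos).sum(0)
            out = constrain_water(pos, masses)
            assert abs(np.linalg.norm(out[1] - out[0]) - w.r_oh) < 1e-6
            assert abs(np.linalg.norm(out[2] - out[0]) - w.r_oh) < 1e-6
            assert abs(np.linalg.norm(out[2] - out[1]) - w.r_hh) < 1e-6
            com_after = (masses[:, None] * out).sum(0)
            assert np.abs(com_after - com_before).max() < 1e-9  # internal impulses

    def test_collinear_geometry_rejected(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(ConstraintError):
            constrain_water(pos, np.array([16.0, 1.0, 1.0]))


class TestRuns:
    def test_zero_production_steps_gives_empty_trajectory(self):
        config = build_fixture("single_ion")
        spec = RunSpec(n_equil_steps=10, n_prod_steps=0, sample_interval=5, mode="mc_primitive")
        traj = run(config, spec)
        assert traj.n_frames == 0
        assert traj.metadata["mode"] == "mc_primitive"
        assert traj.metadata["r_n"] == config.geometry.r_n

    def test_mc_runs_are_bitwise_deterministic(self):
        spec = BuildSpec(concentration=1.3, n_water=1045, n_wall_charges=8, rng_seed=9, explicit_water=False)
        config = build_system(spec)
        rs = RunSpec(n_equil_steps=500, n_prod_steps=5000, sample_interval=500, mode="mc_primitive", rng_seed=5)
        a, b = run(config, rs), run(config, rs)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.potentials, b.potentials)

    def test_md_runs_are_bitwise_deterministic(self):
        geo = PoreGeometry(r_n=10.0, l_z=20.0)
        spec = BuildSpec(concentration=1.0, n_water=10, n_wall_charges=2, rng_seed=6, geometry=geo)
        config = build_system(spec)
        rs = RunSpec(n_equil_steps=100, n_prod_steps=200, sample_interval=50, rng_seed=6)
        a, b = run(config, rs), run(config, rs)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.total_energies, b.total_energies)

    def test_thermostat_holds_target_temperature(self, small_md_config):
        rs = RunSpec(n_equil_steps=2000, n_prod_steps=4000, sample_interval=20, rng_seed=4)
        traj = run(small_md_config, rs)
        assert abs(traj.temperatures.mean() - 298.0) / 298.0 < 0.02

    def test_nve_energy_conservation(self, small_md_config):
        rs = RunSpec(
            n_equil_steps=4000, n_prod_steps=10_000, sample_interval=10,
            rng_seed=4, thermostat=False, coulomb="cutoff_rf", r_cut=8.0,
        )
        traj = run(small_md_config, rs)
        e = traj.total_energies
        assert (e.max() - e.min()) / np.abs(e).mean() < 1e-3

    def test_particle_reaching_wall_aborts_with_index(self):
        from nanopore_edl.sampler import IntegrationError

        config = build_fixture("single_ion")
        config.velocities[0] = [0.5, 0.0, 0.0]  # ballistic toward the wall
        rs = RunSpec(n_equil_steps=0, n_prod_steps=500, sample_interval=100,
                     rng_seed=0, thermostat=False, n_min_steps=0)
        with pytest.raises(IntegrationError, match="0"):
            run(config, rs)

    def test_frame_count_contract(self):
        config = build_fixture("single_ion")
        rs = RunSpec(n_equil_steps=0, n_prod_steps=1000, sample_interval=250, mode="mc_primitive")
        traj = run(config, rs)
        assert traj.n_frames == 4
        assert np.array_equal(traj.wall_positions, config.wall_positions)


class TestMetropolis:
    def test_two_state_occupation_matches_boltzmann(self):
        # toy double well: state energies 0 and du; symmetric proposals
        du, t = 2.0, 298.0
        beta = 1.0 / (KB * t)
        rng = np.random.default_rng(12)
        state, counts = 0, np.zeros(2)
        n = 200_000
        us = rng.random(n)
        for i in range(n):
            trial = 1 - state
            delta = du if trial == 1 else -du
            if metropolis_accept(delta, beta, us[i]):
                state = trial
            counts[state] += 1
        ratio = counts[1] / counts[0]
        expected = np.exp(-beta * du)
        # binomial-scale tolerance on the occupation fraction
        p = expected / (1 + expected)
        se = 3 * np.sqrt(p * (1 - p) / n) * 10  # inflate for chain correlation
        assert abs(counts[1] / n - p) < se

    def test_always_accept_downhill(self):
        assert metropolis_accept(-1.0, 1.0, 0.999999)
        assert metropolis_accept(0.0, 1.0, 0.999999)
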