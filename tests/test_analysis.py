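"""Analysis tests: density binning and closure, screening factor, radial
potential, and peak location."""

import numpy as np
import pytest

from nanopore_edl.analysis import (
    RadialProfile,
    first_overscreening_radius,
    locate_peaks,
    radial_density,
    radial_potential,
    screening_factor,
)
from nanopore_edl.builder import build_fixture
from nanopore_edl.constants import A3_TO_L, AVOGADRO, COULOMB_VOLT, FARADAY
from nanopore_edl.sampler import Trajectory
from nanopore_edl.system import PoreGeometry


def traj_from_positions(frames, species, geo, wall_positions=None, metadata=None):
    frames = np.asarray(frames, dtype=float)
    nf = len(frames)
    wall = np.zeros((0, 3)) if wall_positions is None else np.asarray(wall_positions, dtype=float)
    return Trajectory(
        frames=frames,
        temperatures=np.full(nf, 298.0),
        potentials=np.zeros(nf),
        total_energies=np.zeros(nf),
        species=list(species),
        mol_id=np.arange(len(species)),
        wall_positions=wall,
        wall_charges=np.full(len(wall), -1.0),
        geometry=geo,
        metadata=metadata or {},
    )


def make_profile(edges, conc, geo, species="Na+"):
    return RadialProfile(
        edges=np.asarray(edges, dtype=float),
        concentration=np.asarray(conc, dtype=float),
        counts_mean=np.zeros(len(conc)),
        stderr=np.zeros(len(conc)),
        species=species,
        n_frames=1,
        geometry=geo,
    )


class TestRadialDensity:
    def test_ideal_gas_profile_is_flat(self):
        config = build_fixture("ideal_gas", n=4000, seed=8)
        traj = traj_from_positions([config.positions], config.species, config.geometry)
        prof = radial_density(traj, "TRACER", bin_width=3.0)
        n = 4000
        p = prof.shell_volumes / (np.pi * config.geometry.r_n**2 * config.geometry.l_z)
        expected = n * p
        z = (prof.counts_mean - expected) / np.sqrt(expected * (1 - p))
        assert np.abs(z).max() < 3.0

    def test_count_closure(self, mc_production):
        _, traj = mc_production
        for sp in ("Na+", "Cl-"):
            prof = radial_density(traj, sp, bin_width=0.25)
            expected = np.mean([sum(1 for s in traj.species if s == sp)])
            assert prof.mean_count() == pytest.approx(expected, rel=1e-9)

    def test_absent_species_gives_zero_profile(self, mc_production):
        _, traj = mc_production
        prof = radial_density(traj, "O", bin_width=1.0)
        assert not prof.concentration.any()

    def test_empty_trajectory_rejected(self):
        geo = PoreGeometry()
        traj = traj_from_positions(np.zeros((0, 0, 3)), [], geo)
        with pytest.raises(ValueError):
            radial_density(traj, "Na+", 0.5)


class TestScreeningFactor:
    def test_identical_profiles_give_zero(self):
        geo = PoreGeometry(r_n=30.0, l_z=14.0)
        edges = np.linspace(0, 30, 31)
        c = np.random.default_rng(0).uniform(0, 2, 30)
        sf = screening_factor(make_profile(edges, c, geo), make_profile(edges, c, geo), sigma_s=0.05)
        assert not sf.s_f.any()

    def test_wall_edge_is_zero_exactly(self, mc_production):
        config, traj = mc_production
        na = radial_density(traj, "Na+", 0.5)
        cl = radial_density(traj, "Cl-", 0.5)
        sf = screening_factor(na, cl, config.sigma_s)
        assert sf.s_f[-1] == 0.0

    def test_electroneutral_run_closes_to_one_at_axis(self, mc_production):
        config, traj = mc_production
        na = radial_density(traj, "Na+", 0.5)
        cl = radial_density(traj, "Cl-", 0.5)
        sf = screening_factor(na, cl, config.sigma_s)
        assert sf.value_at_axis() == pytest.approx(1.0, abs=1e-3)

    def test_single_shell_step_profile_hand_integral(self):
        # counterions only, uniform C0 in one shell [a, b]
        geo = PoreGeometry(r_n=30.0, l_z=14.0)
        edges = np.linspace(0, 30, 31)
        conc = np.zeros(30)
        conc[20] = 1.5  # shell 20-21 Å
        zero = np.zeros(30)
        sigma_s = 0.05
        sf = screening_factor(make_profile(edges, conc, geo), make_profile(edges, zero, geo), sigma_s)
        a, b, rn = 20e-10, 21e-10, 30e-10
        expected = FARADAY * 1.5e3 * (b**2 - a**2) / (2 * rn) / sigma_s
        assert sf.s_f[0] == pytest.approx(expected, rel=1e-12)
        assert sf.s_f[20] == pytest.approx(expected, rel=1e-12)  # inner edge of the shell
        assert sf.s_f[21] == 0.0  # outer edge: nothing beyond

    def test_planar_switch_drops_jacobian(self):
        geo = PoreGeometry(r_n=30.0, l_z=14.0)
        edges = np.linspace(0, 30, 31)
        conc = np.zeros(30)
        conc[20] = 1.5
        zero = np.zeros(30)
        sf = screening_factor(make_profile(edges, conc, geo), make_profile(edges, zero, geo), 0.05, planar=True)
        expected = FARADAY * 1.5e3 * 1e-10 / 0.05
        assert sf.s_f[0] == pytest.approx(expected, rel=1e-12)

    def test_mismatched_bins_rejected(self):
        geo = PoreGeometry()
        a = make_profile(np.linspace(0, 30, 31), np.zeros(30), geo)
        b = make_profile(np.linspace(0, 30, 16), np.zeros(15), geo)
        with pytest.raises(ValueError):
            screening_factor(a, b, 0.05)

    def test_zero_sigma_rejected(self):
        geo = PoreGeometry()
        a = make_profile(np.linspace(0, 30, 31), np.zeros(30), geo)
        with pytest.raises(ValueError):
            screening_factor(a, a, 0.0)

    def test_no_overscreening_returns_none(self):
        geo = PoreGeometry()
        edges = np.linspace(0, 30, 31)
        conc = np.full(30, 0.01)
        sf = screening_factor(make_profile(edges, conc, geo), make_profile(edges, np.zeros(30), geo), 1.0)
        assert sf.s_f.max() < 1.0
        assert first_overscreening_radius(sf) is None


class TestRadialPotential:
    def test_unchanged_system_gives_zero(self):
        config = build_fixture("ideal_gas", n=50, seed=1)
        traj = traj_from_positions([config.positions], config.species, config.geometry)
        prof = radial_potential(traj, bin_width=5.0)
        assert np.abs(prof.phi).max() == 0.0

    def test_axis_reference_is_zero_exactly(self, mc_production):
        _, traj = mc_production
        sub = traj_from_positions(traj.frames[:3], traj.species, traj.geometry, traj.wall_positions)
        prof = radial_potential(sub, radii=np.array([0.0]))
        assert prof.phi[0] == 0.0

    def test_single_wall_charge_hand_evaluation(self):
        # one -1 e frozen charge; probes against the on-axis reference,
        # replicated here with independent loops
        geo = PoreGeometry(r_n=10.0, l_z=50.0)
        wall = np.array([[10.0, 0.0, 25.0]])
        traj = traj_from_positions(np.zeros((1, 0, 3)), [], geo, wall_positions=wall)
        n_az, n_ax = 8, 4
        prof = radial_potential(traj, radii=np.array([4.0]), n_azimuthal=n_az, n_axial=n_ax)
        theta = (np.arange(n_az) + 0.5) * 2 * np.pi / n_az
        zp = (np.arange(n_ax) + 0.5) * geo.l_z / n_ax
        acc = []
        for th in theta:
            for z in zp:
                p = np.array([4.0 * np.cos(th), 4.0 * np.sin(th), z])
                dz = p[2] - 25.0
                dz -= 50.0 * np.round(dz / 50.0)
                d = np.sqrt((p[0] - 10.0) ** 2 + p[1] ** 2 + dz**2)
                dz0 = z - 25.0
                dz0 -= 50.0 * np.round(dz0 / 50.0)
                d0 = np.sqrt(100.0 + dz0**2)
                acc.append(-1.0 * (1 / d - 1 / d0))
        assert prof.phi[0] == pytest.approx(COULOMB_VOLT * np.mean(acc), rel=1e-10)

    def test_probe_on_charge_is_excluded(self):
        geo = PoreGeometry(r_n=10.0, l_z=8.0)
        # mobile ion parked exactly on a probe ring position
        th = (0 + 0.5) * 2 * np.pi / 4
        z = (0 + 0.5) * 8.0 / 2
        pos = np.array([[4.0 * np.cos(th), 4.0 * np.sin(th), z]])
        traj = traj_from_positions([pos], ["Na+"], geo)
        prof = radial_potential(traj, radii=np.array([4.0]), n_azimuthal=4, n_axial=2)
        assert prof.n_excluded >= 1


class TestPeaks:
    def geo(self):
        return PoreGeometry(r_n=30.0, l_z=14.0)

    def test_single_bin_spike(self):
        edges = np.linspace(0, 30, 61)
        conc = np.zeros(60)
        conc[55] = 3.0
        report = locate_peaks(make_profile(edges, conc, self.geo()))
        assert report.found
        assert report.wall_distance == pytest.approx(30.0 - (edges[55] + edges[56]) / 2)

    def test_monotone_profile_peaks_at_boundary_without_valley(self):
        edges = np.linspace(0, 30, 31)
        conc = np.linspace(0.1, 2.0, 30)
        report = locate_peaks(make_profile(edges, conc, self.geo()))
        assert report.found
        assert report.r_peak == pytest.approx(29.5)
        assert not report.valley_found

    def test_two_gaussian_recovery_within_bin_width(self):
        bw = 0.25
        edges = np.arange(0, 30 + bw / 2, bw)
        centers = 0.5 * (edges[:-1] + edges[1:])
        c1, c2 = 28.5, 26.5  # Å from axis
        conc = 4 * np.exp(-((centers - c1) ** 2) / 0.18) + 2 * np.exp(-((centers - c2) ** 2) / 0.18)
        report = locate_peaks(make_profile(edges, conc, self.geo()))
        assert abs(report.r_peak - c1) <= bw
        assert report.valley_found
        assert c2 < report.r_valley < c1  # valley between the two modes

    def test_all_zero_profile_flagged_not_error(self):
        edges = np.linspace(0, 30, 31)
        report = locate_peaks(make_profile(edges, np.zeros(30), self.geo()))
        assert not report.found

    def test_too_few_bins_rejected(self):
        edges = np.linspace(0, 30, 3)
        with pytest.raises(ValueError):
            locate_peaks(make_profile(edges, np.zeros(2), self.geo()))
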