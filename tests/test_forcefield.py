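"""Force-field unit tests: combining rules, LJ, Steele wall, parameter I/O."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopore_edl.forcefield import (
    ParameterError,
    SpeciesParams,
    WallModel,
    combine_lorentz_berthelot,
    default_forcefield,
    lj_energy,
    lj_energy_force,
    load_forcefield,
)

# published pure-pair LJ table (sigma Å, epsilon kJ/mol)
PURE = {"Na+": (2.583, 0.4184), "Cl-": (4.401, 0.4184), "O": (3.169, 0.6502)}
# mixed rows the combining rules must reproduce at printed precision
MIXED = {
    ("Na+", "Cl-"): (3.492, 0.4184),
    ("Na+", "O"): (2.876, 0.5216),
    ("Cl-", "O"): (3.785, 0.5216),
}


class TestCombiningRules:
    @pytest.mark.parametrize(("pair", "expected"), MIXED.items(), ids=["NaCl", "NaO", "ClO"])
    def test_reproduces_published_mixed_rows(self, ff, pair, expected):
        p = combine_lorentz_berthelot(ff[pair[0]], ff[pair[1]])
        assert p.sigma_ij == pytest.approx(expected[0], abs=5e-4)
        assert p.epsilon_ij == pytest.approx(expected[1], abs=5e-5)

    def test_identity_on_like_pairs(self, ff):
        for name in PURE:
            p = combine_lorentz_berthelot(ff[name], ff[name])
            assert (p.sigma_ij, p.epsilon_ij) == (ff[name].sigma, ff[name].epsilon)

    @settings(deadline=None, max_examples=50)
    @given(
        s1=st.floats(0.5, 10), s2=st.floats(0.5, 10),
        e1=st.floats(0.0, 5), e2=st.floats(0.0, 5),
    )
    def test_mixing_is_symmetric_and_bounded(self, s1, s2, e1, e2):
        a = SpeciesParams("A", 1.0, 0.0, s1, e1)
        b = SpeciesParams("B", 1.0, 0.0, s2, e2)
        p, q = combine_lorentz_berthelot(a, b), combine_lorentz_berthelot(b, a)
        assert p == q
        assert min(s1, s2) <= p.sigma_ij <= max(s1, s2)
        assert p.epsilon_ij <= max(e1, e2)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            SpeciesParams("bad", 1.0, 0.0, 3.0, -0.1)


class TestLennardJones:
    def test_zero_crossing_and_minimum(self, ff):
        p = ff.pair("Na+", "Cl-")
        assert lj_energy(p.sigma_ij, p.sigma_ij, p.epsilon_ij) == pytest.approx(0.0, abs=1e-12)
        rmin = 2 ** (1 / 6) * p.sigma_ij
        u, f = lj_energy_force(rmin, p.sigma_ij, p.epsilon_ij)
        assert u == pytest.approx(-p.epsilon_ij, rel=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_value(self):
        # direct arithmetic with the published Na+/Cl- mixed parameters
        sigma, eps, r = 3.492, 0.4184, 3.0
        sr6 = (sigma / r) ** 6
        expected = 4.0 * eps * (sr6**2 - sr6)
        assert lj_energy(r, sigma, eps) == pytest.approx(expected, rel=1e-12)

    def test_force_matches_finite_difference(self):
        sigma, eps, h = 3.492, 0.4184, 1e-6
        for r in (3.0, 3.9, 5.5):
            _, f = lj_energy_force(r, sigma, eps)
            fd = -(lj_energy(r + h, sigma, eps) - lj_energy(r - h, sigma, eps)) / (2 * h)
            assert f == pytest.approx(fd, rel=1e-6)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 3.0, 0.5)


class TestSteeleWall:
    def test_repulsive_divergence_at_wall(self, ff):
        wall = dataclasses.replace(ff.wall, r_n=30.0)
        assert wall.steele_energy(30.0 - 1e-3, ff["Na+"]) > 1e10

    def test_minimum_from_grid_scan(self, ff):
        # independent oracle: dense 1-D scan at 1e-3 Å resolution
        wall = dataclasses.replace(ff.wall, r_n=30.0)
        r = np.arange(1e-3, 30.0 - 1e-3, 1e-3)
        u = wall.steele_energy(r, ff["Na+"])
        i = int(u.argmin())
        z_star = 30.0 - r[i]
        assert u[i] < 0.0
        assert 1.0 < z_star < 5.0  # minimum sits a few Å off the wall
        # analytic force vanishes at the scanned minimum
        _, f = wall.steele_energy_force(r[i], ff["Na+"])
        assert abs(f) < 1e-2
        # inward of the minimum the attraction decays monotonically in
        # magnitude toward the pore axis (all still negative)
        inner = u[r < r[i] - 1.0]
        assert np.all(inner < 0.0)
        assert np.all(np.diff(np.abs(inner[::1000])) > 0.0)

    def test_force_matches_finite_difference(self, ff):
        wall = dataclasses.replace(ff.wall, r_n=30.0)
        h = 1e-6
        for r in (26.0, 27.2, 20.0, 5.0):
            _, f = wall.steele_energy_force(r, ff["Na+"])
            fd = -(wall.steele_energy(r + h, ff["Na+"]) - wall.steele_energy(r - h, ff["Na+"])) / (2 * h)
            assert f == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_domain_error_outside_pore(self, ff):
        wall = dataclasses.replace(ff.wall, r_n=30.0)
        with pytest.raises(ValueError):
            wall.steele_energy(30.0, ff["Na+"])

    def test_planar_limit_of_large_pore(self, ff):
        # the cylindrical form depends on position only through r_n - r, so
        # a huge pore evaluated at fixed wall distance equals the flat wall
        wall = dataclasses.replace(ff.wall, r_n=1.0e6)
        for z in (2.0, 3.0, 8.0):
            cyl = wall.steele_energy(1.0e6 - z, ff["O"])
            flat = wall.planar_1043_energy(z, ff["O"])
            assert cyl == pytest.approx(flat, rel=1e-9)

    def test_hydrogen_feels_no_wall(self, ff):
        wall = dataclasses.replace(ff.wall, r_n=30.0)
        assert wall.steele_energy(29.0, ff["H"]) == 0.0


class TestParameterFile:
    def test_default_file_reproduces_published_table(self, ff):
        for name, (sigma, eps) in PURE.items():
            assert ff[name].sigma == sigma
            assert ff[name].epsilon == eps

    def test_water_is_neutral_and_rigid_geometry(self, ff):
        w = ff.water
        assert w.q_o + 2 * w.q_h == pytest.approx(0.0, abs=1e-12)
        assert w.r_hh == pytest.approx(2 * w.r_oh * math.sin(math.radians(w.angle_hoh) / 2))

    def test_round_trip_through_custom_file(self, tmp_path, ff):
        import importlib.resources as res

        text = res.files("nanopore_edl.data").joinpath("forcefield.ini").read_text()
        p = tmp_path / "ff.ini"
        p.write_text(text)
        ff2 = load_forcefield(p)
        assert ff2["Na+"] == ff["Na+"]
        assert ff2.wall.sigma_w == ff.wall.sigma_w

    def test_missing_species_rejected(self, tmp_path):
        p = tmp_path / "bad.ini"
        p.write_text("[species.O]\nmass=16\ncharge=0\nsigma=3\nepsilon=0.6\n")
        with pytest.raises(ParameterError):
            load_forcefield(p)

    def test_wall_constants_positive(self):
        with pytest.raises(ParameterError):
            WallModel(r_n=-1.0)
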