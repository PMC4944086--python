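"""Electric-double-layer analysis of pore trajectories.

Three result surfaces:

* radial concentration profiles C_i(r) in mol/L, from cylindrical-shell
  binning of production frames;
* the screening factor S_f(r) — cumulative mobile net charge per unit
  wall area between the wall and radius r, normalized by the surface
  charge density (S_f > 1 marks overscreening);
* the radial electrostatic potential phi(r) from direct Coulomb
  superposition over all charges, referenced to zero on the pore axis.

Peak reporting gives wall distances (r_n - r) so results read as
"x Å away from the charged wall".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import A3_TO_L, AVOGADRO, COULOMB_VOLT, FARADAY
from .forcefield import ForceField, default_forcefield
from .sampler import Trajectory
from .system import PoreGeometry

__all__ = [
    "RadialProfile",
    "ScreeningProfile",
    "PotentialProfile",
    "PeakReport",
    "radial_density",
    "screening_factor",
    "radial_potential",
    "locate_peaks",
    "first_overscreening_radius",
]


@dataclass
class RadialProfile:
    """Binned radial concentration of one species, averaged over frames."""

    edges: np.ndarray  # (n_bins + 1,) Å, from the axis outward
    concentration: np.ndarray  # (n_bins,) mol/L
    counts_mean: np.ndarray  # mean particles per frame per bin
    stderr: np.ndarray  # mol/L, standard error over frames
    species: str
    n_frames: int
    geometry: PoreGeometry

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def wall_distances(self) -> np.ndarray:
        """Distance of each bin center from the wall, r_n - r."""
        return self.geometry.r_n - self.centers

    @property
    def shell_volumes(self) -> np.ndarray:
        """Cylindrical shell volumes in Å^3."""
        return np.pi * (self.edges[1:] ** 2 - self.edges[:-1] ** 2) * self.geometry.l_z

    def mean_count(self) -> float:
        """Closure check: sum_bins C * V * N_A, the mean count per frame."""
        return float(np.sum(self.concentration * self.shell_volumes * A3_TO_L * AVOGADRO))


@dataclass
class ScreeningProfile:
    """S_f evaluated at the bin edges, integrating inward from the wall."""

    radii: np.ndarray  # (n_bins + 1,) Å; radii[-1] == r_n
    s_f: np.ndarray  # dimensionless, same length
    sigma_s: float  # C/m^2
    planar: bool = False

    def value_at_axis(self) -> float:
        return float(self.s_f[0])


@dataclass
class PotentialProfile:
    """Azimuth/axially averaged radial potential, zero on the axis."""

    radii: np.ndarray  # Å, bin centers
    phi: np.ndarray  # V
    n_excluded: int  # probe samples dropped for sitting on a charge


@dataclass
class PeakReport:
    """Location/height of the global density maximum and the first valley."""

    found: bool
    r_peak: float = np.nan
    wall_distance: float = np.nan  # r_n - r_peak
    height: float = np.nan  # mol/L
    valley_found: bool = False
    r_valley: float = np.nan
    valley_wall_distance: float = np.nan
    valley_height: float = np.nan


def radial_density(traj: Trajectory, species: str, bin_width: float = 0.25,
                   forcefield: ForceField | None = None) -> RadialProfile:
    """Per-frame cylindrical-shell histogram of one species, in mol/L.

    Raises on an empty trajectory; an absent species yields an all-zero
    profile.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    geo = traj.geometry
    n_bins = max(1, int(np.ceil(geo.r_n / bin_width)))
    edges = np.linspace(0.0, geo.r_n, n_bins + 1)
    sel = np.array([s == species for s in traj.species])
    counts = np.zeros((traj.n_frames, n_bins))
    if sel.any():
        for k in range(traj.n_frames):
            r = np.hypot(traj.frames[k, sel, 0], traj.frames[k, sel, 1])
            counts[k] = np.histogram(r, bins=edges)[0]
    shell_v = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * geo.l_z  # Å^3
    to_conc = 1.0 / (shell_v * A3_TO_L * AVOGADRO)
    conc_frames = counts * to_conc[None, :]
    conc = conc_frames.mean(axis=0)
    stderr = conc_frames.std(axis=0) / np.sqrt(max(1, traj.n_frames))
    return RadialProfile(
        edges=edges,
        concentration=conc,
        counts_mean=counts.mean(axis=0),
        stderr=stderr,
        species=species,
        n_frames=traj.n_frames,
        geometry=geo,
    )


def screening_factor(na_profile: RadialProfile, cl_profile: RadialProfile,
                     sigma_s: float, planar: bool = False) -> ScreeningProfile:
    """Cumulative net mobile charge per wall area, normalized by sigma_s.

    S_f(r) = (1/sigma_s) * int_r^{r_n} F [C_Na(r') - C_Cl(r')] (r'/r_n) dr'

    The r'/r_n factor converts shell charge to charge per unit wall area
    in the cylindrical geometry, so S_f(0) -> 1 for any electroneutral
    system; ``planar=True`` drops it, reproducing the flat-wall form of
    the integral.  Bins are integrated exactly as piecewise-constant
    concentrations.  S_f(r_n) = 0 identically.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if not np.array_equal(na_profile.edges, cl_profile.edges):
        raise ValueError("profiles must share identical bins")
    edges_m = na_profile.edges * 1.0e-10
    r_n_m = na_profile.geometry.r_n * 1.0e-10
    dc = (na_profile.concentration - cl_profile.concentration) * 1.0e3  # mol/m^3
    if planar:
        w = np.diff(edges_m)
    else:
        w = (edges_m[1:] ** 2 - edges_m[:-1] ** 2) / (2.0 * r_n_m)
    per_bin = FARADAY * dc * w  # C/m^2 per bin
    s_f = np.zeros(len(edges_m))
    s_f[:-1] = np.cumsum(per_bin[::-1])[::-1] / sigma_s
    return ScreeningProfile(radii=na_profile.edges.copy(), s_f=s_f, sigma_s=sigma_s, planar=planar)


def first_overscreening_radius(profile: ScreeningProfile) -> float | None:
    """Largest radius at which S_f reaches 1 (closest point to the wall).

    Returns None when the surface charge is never overscreened.  Linear
    interpolation between bin edges.
    """
    r, s = profile.radii, profile.s_f
    for i in range(len(s) - 1, 0, -1):
        s_out, s_in = s[i], s[i - 1]  # outer edge (wallward) and inner edge
        if (s_out - 1.0) * (s_in - 1.0) <= 0.0 and s_out != s_in:
            t = (1.0 - s_out) / (s_in - s_out)
            return float(r[i] + t * (r[i - 1] - r[i]))
    return None


def radial_potential(
    traj: Trajectory,
    bin_width: float = 0.5,
    n_azimuthal: int = 64,
    n_axial: int = 8,
    frame_stride: int = 1,
    min_distance: float = 0.5,
    forcefield: ForceField | None = None,
    radii: np.ndarray | None = None,
) -> PotentialProfile:
    """phi(r) in volts by direct Coulomb superposition over all charges.

    For each probe radius, ``n_azimuthal x n_axial`` probe points are
    paired with an on-axis reference at the same z, so the reported value
    is phi(r) - phi(axis) and phi(0) = 0 by construction.  Minimum-image
    convention along z; probe samples closer than ``min_distance`` to any
    charge are excluded from the average.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ff = forcefield or default_forcefield()
    geo = traj.geometry
    q_mobile = traj.charges(ff)
    charged = q_mobile != 0.0
    if radii is None:
        n_bins = max(1, int(np.ceil(geo.r_n / bin_width)))
        radii = (np.arange(n_bins) + 0.5) * geo.r_n / n_bins
    else:
        radii = np.asarray(radii, dtype=float)
        n_bins = len(radii)

    theta = (np.arange(n_azimuthal) + 0.5) * 2.0 * np.pi / n_azimuthal
    z_probe = (np.arange(n_axial) + 0.5) * geo.l_z / n_axial
    # probe grid (one set per radius): (n_probe, 3)
    tt, zz = np.meshgrid(theta, z_probe, indexing="ij")
    tt, zz = tt.ravel(), zz.ravel()
    n_probe = len(tt)

    phi = np.zeros(n_bins)
    n_samples = np.zeros(n_bins)
    n_excluded = 0
    l_z = geo.l_z

    frame_ids = range(0, traj.n_frames, max(1, frame_stride))
    for k in frame_ids:
        srcs = [traj.frames[k][charged]]
        qs = [q_mobile[charged]]
        if len(traj.wall_positions):
            srcs.append(traj.wall_positions)
            qs.append(traj.wall_charges)
        src = np.vstack(srcs)
        q = np.concatenate(qs)
        # reference (on-axis) distances depend only on z of the probe
        ref = np.zeros((n_axial, 3))
        ref[:, 2] = z_probe
        dref = ref[:, None, :] - src[None, :, :]
        dref[:, :, 2] -= l_z * np.round(dref[:, :, 2] / l_z)
        rref = np.sqrt(np.sum(dref**2, axis=2))  # (n_axial, n_src)
        ref_ok = np.all(rref >= min_distance, axis=1)
        inv_ref = np.where(rref < min_distance, 0.0, 1.0 / np.maximum(rref, min_distance))
        phi_ref = inv_ref @ q  # (n_axial,)
        for b, rp in enumerate(radii):
            probe = np.column_stack([rp * np.cos(tt), rp * np.sin(tt), zz])
            d = probe[:, None, :] - src[None, :, :]
            d[:, :, 2] -= l_z * np.round(d[:, :, 2] / l_z)
            rr = np.sqrt(np.sum(d**2, axis=2))
            ok = np.all(rr >= min_distance, axis=1)
            zi = (np.arange(n_probe) % n_axial)
            ok &= ref_ok[zi]
            n_excluded += int(n_probe - ok.sum())
            if not ok.any():
                continue
            phi_p = (1.0 / rr[ok]) @ q
            phi[b] += float(np.sum(phi_p - phi_ref[zi[ok]]))
            n_samples[b] += ok.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(n_samples > 0, phi / np.maximum(n_samples, 1), 0.0)
    return PotentialProfile(radii=radii, phi=COULOMB_VOLT * phi, n_excluded=n_excluded)


def locate_peaks(profile: RadialProfile) -> PeakReport:
    """Global maximum (as wall distance) and the first valley inward of it.

    The valley is the first local minimum encountered moving from the
    peak toward the axis, supporting statements like "the coion maximum
    sits in the first counterion valley".  An all-zero profile yields a
    flagged no-peak report.
    """
    c = profile.concentration
    if len(c) < 3:
        raise ValueError("need at least 3 bins to locate peaks")
    if not np.any(c > 0):
        return PeakReport(found=False)
    centers = profile.centers
    i_pk = int(np.argmax(c))
    report = PeakReport(
        found=True,
        r_peak=float(centers[i_pk]),
        wall_distance=float(profile.geometry.r_n - centers[i_pk]),
        height=float(c[i_pk]),
    )
    # walk inward (toward the axis = decreasing index) looking for a local minimum
    for i in range(i_pk - 1, 0, -1):
        if c[i] <= c[i + 1] and c[i] <= c[i - 1]:
            report.valley_found = True
            report.r_valley = float(centers[i])
            report.valley_wall_distance = float(profile.geometry.r_n - centers[i])
            report.valley_height = float(c[i])
            break
    return report
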