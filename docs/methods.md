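# Methods

## The physical model

The package simulates aqueous NaCl confined in an infinite cylindrical
nanopore whose wall carries frozen negative elementary charges, and
measures the structure of the resulting electric double layer (EDL).
Three interaction terms define the energy surface:

1. **Pairwise Lennard-Jones** between all LJ-active sites (water oxygen,
   Na+, Cl-).  Pure-pair parameters live in a plain-text table
   (`data/forcefield.ini`); unlike pairs use Lorentz-Berthelot mixing —
   arithmetic-mean sigma, geometric-mean epsilon.  Hydrogens and wall
   charges carry no LJ term.
2. **Coulomb electrostatics** among mobile charges and between mobile
   charges and the frozen wall sites, with internal Coulomb constant
   1389.35458 kJ Å/(mol e²).  Three evaluation routes exist (below).
3. **The Steele 10-4-3 wall**, the laterally averaged LJ interaction of a
   layered solid, applied as a function of wall distance z = R_n − r:

       u_wf(z) = 2π ρ_w ε_wf σ_wf² Δ [ (2/5)(σ_wf/z)¹⁰ − (σ_wf/z)⁴
                  − σ_wf⁴ / (3Δ (z + 0.61Δ)³) ]

   with Δ = 2.709 Å, ρ_w = 42.76 nm⁻³ (converted to Å⁻³ internally),
   and wall-fluid parameters mixed Lorentz-Berthelot from the bulk-silica
   values σ_w = 3.0 Å, ε_w/k_B = 230 K.  Because the form depends on
   position only through z it applies unchanged to any pore radius, and a
   huge pore reproduces the flat-wall 10-4-3 potential exactly — a
   property the tests exploit.

Water is rigid three-site SPC/E: q_O = −0.8476 e, q_H = +0.4238 e,
r_OH = 1.0 Å, H-O-H = 109.47°, LJ on oxygen only — the standard
SPC/E definition.

Internal units are Å, g/mol, kJ/mol, fs, elementary charges.

### Electroneutrality and the builder

Ion counts derive from the nominal molarity through the ion/water ratio
(c/55.345 pairs per water); each −1 e wall charge is compensated by one
extra Na+, so every built cell is exactly neutral by integer bookkeeping.
Wall charges sit exactly on the cylinder r = R_n, equally spaced in z
with seeded random azimuths.  Particles are placed by rejection sampling
inside r < R_n − 1 Å with no two LJ centers closer than 0.8 σ_ij; builds
are pure functions of their spec (including the seed).

The pore is fully periodic along z.  The default repeat length is
L_z = 14 Å, chosen so the standard filling (1045 waters plus ions in the
30 Å-radius pore) sits near liquid-water density (≈0.033 Å⁻³); the
reservoir-coupled device geometry is out of scope, so the
periodic pore is the model system throughout.

### Electrostatics routes

* `bare` — full minimum-image 1/r along z.  Used by the implicit-solvent
  mode and small-fixture oracles.  Its force is discontinuous where a
  pair crosses |dz| = L_z/2, which is harmless for Monte Carlo but makes
  it a poor choice for long NVE dynamics.
* `cutoff_rf` — conductor-like reaction field: u ∝ 1/r + r²/(2r_c³) −
  3/(2r_c), with both energy and force vanishing smoothly at the cutoff
  (≤ L_z/2).  The production route for explicit-water dynamics.
* `ewald` — standard 3D Ewald (real + reciprocal + self + intramolecular
  exclusion correction) with the quasi-1D pore embedded in an
  orthorhombic cell with lateral vacuum padding (box 4R_n × 4R_n × L_z).
  Requires a neutral cell.  Used for validation (it reproduces the
  rock-salt Madelung energy to <1e-3 against an independent Evjen direct
  sum) and available for small production systems; the reaction-field
  route is the default because a per-step Ewald at these paddings is not
  desk-scale.

### Dynamics

Velocity Verlet at dt = 2 fs; Berendsen weak coupling to T0 = 298.0 K
with τ = 0.1 ps (λ = sqrt(1 + (dt/τ)(T0/T − 1)), applied to all mobile
velocities jointly).  Equilibration is always thermostatted; the
production phase honours the `thermostat` flag, so NVE measurements
start from an equilibrated state.  Rigid water uses iterative
SHAKE (positions, against the pre-drift reference bonds) and RATTLE
(velocity projection), converged to 1e-10 on the squared distances —
four orders tighter than the 1e-6 Å contract; constraint impulses are
internal, conserving momentum.  Instantaneous temperature counts
3N − 3 − 3·n_water degrees of freedom.  Velocities initialize
Maxwell-Boltzmann at T0 with the center-of-mass drift removed.

Fresh builds contain hard contacts (randomly oriented hydrogens), so MD
runs begin with capped steepest descent (0.05 Å maximum displacement,
constraints re-imposed each step) until the largest force falls below
100 kJ/(mol Å).

### Implicit-solvent Monte Carlo (fast mode)

`mc_primitive` drops the waters and treats them as a uniform dielectric
(ε_r = 78.4), keeping ion LJ, the Steele wall, and wall-charge Coulomb
(all electrostatics scaled 1/ε_r, bare minimum-image along z).
Single-particle cubic displacement moves (default edge 2 Å; trial radii
within 0.2 Å of the wall are rejected outright) with Metropolis
acceptance.  All random variates are pre-drawn from a seeded PCG64
generator, so chains are bitwise reproducible.  This mode is an artifact
addition — the reference protocol is explicit-water MD — introduced to make
equilibrium EDL properties testable in minutes; the single-ion run
against the exact r·exp(−βu_wf) law is its calibration.

### Hierarchical equilibration for explicit water

The slow processes in the explicit system are ionic migration to the
wall (several Å of diffusion, tens of ps per Å) and counterion
condensation onto the discrete wall charges (a desolvation barrier).
Desk-scale runs therefore equilibrate hierarchically
(`protocols.hierarchical_equilibrate`): the ionic structure is relaxed
first with the implicit-solvent chain at the bulk permittivity, then a
short reduced-permittivity anneal (ε_r = 10, mid-range for the first
water layers at a charged oxide surface, where the dielectric response
is strongly reduced) lets counterions condense onto the wall-charge
sites as they do under full Coulomb coupling; the relaxed ions are then
solvated with rigid waters (`builder.solvate`, same rejection rules) and
explicit MD refines locally.  This reuses only the package's own
machinery and is how the scaled-down peak-position experiment is run.

## Analysis definitions

* **Radial concentration** C_i(r): per-frame counts in cylindrical
  shells, averaged over frames, divided by shell volume
  π(r_out² − r_in²)L_z and converted to mol/L.  The closure
  Σ C V N_A = mean count per frame holds to round-off on every
  trajectory.
* **Screening factor**: S_f(r) = (1/σ_s) ∫_r^{R_n} F (C_Na − C_Cl)
  (r'/R_n) dr', with σ_s = n_wall·e/(2πR_nL_z) recorded by the builder
  and never hard-coded.  The r'/R_n factor is the cylindrical Jacobian
  expressing cumulative mobile charge per unit *wall* area; without it
  (the literal flat-wall form, available via `planar=True`) the integral
  cannot close to 1 at the axis.  Bins are integrated exactly as
  piecewise-constant concentrations, so S_f(0) = 1 to round-off for any
  electroneutral run and S_f(R_n) = 0 identically.  S_f(r) > 1 is
  overscreening; the reported "overscreening distance" is R_n minus the
  largest radius where S_f reaches 1 (linear interpolation between bin
  edges).
* **Radial potential** φ(r): direct Coulomb superposition
  φ = C Σ_i q_i (1/|x − x_i| − 1/|x₀ − x_i|) over all mobile charge
  sites and wall charges, minimum image along z, with C = 14.399645 V Å/e.
  Each probe (default 64 azimuths × 8 axial stations per radius) pairs
  with an on-axis reference at the same z, so φ(axis) = 0 exactly by
  construction.  Probe samples closer than 0.5 Å to any charge are
  excluded and counted.
* **Peaks**: the global maximum bin, reported as wall distance
  R_n − r_center, plus the first local minimum inward of the peak (the
  "first valley", where the coion layer sits).

## Problem sizes and defaults

| parameter | default | note |
|---|---|---|
| pore radius R_n | 30 Å | reference geometry |
| periodic length L_z | 14 Å | near-liquid density for 1045 waters |
| waters | 1045 | reference filling |
| concentrations | 0.6 / 1.3 / 2.0 M | nominal, via ion/water ratio |
| wall charges | 8 | σ_s ≈ 0.049 C/m², moderate; configurable |
| dt, T0, τ | 2 fs, 298.0 K, 0.1 ps | reference integrator settings |
| bin width | 0.25 Å (densities), 0.5 Å (potential) | resolves the 1.5/3.5 Å structure |

The full-length reference protocol (4 ns + 4 ns explicit water) is
cluster-scale; the package's own validation runs are scaled
down as follows, as a deliberate design choice.  The implicit-solvent
concentration series runs 1.5M moves per (concentration, seed) in the
full 30 Å geometry.  The explicit-water peak experiment uses a reduced
pore (R_n = 20 Å, L_z = 12 Å, 400 waters, 10 wall charges → σ_s ≈
0.106 C/m², a typical silica-like charge density) — legitimate because
the Steele wall and the EDL are local to the wall, while the axis region
only provides the reference bulk — with hierarchical pre-equilibration,
40 ps of thermostatted explicit equilibration and 100 ps of production.
Run lengths are spec fields, so the full schedule is a configuration
choice, not a code change.

## What the generator does and does not emulate

The builder reproduces the reference conditions (geometry, filling,
electroneutral counting, frozen wall charges along z) but replaces the
bulk-reservoir-coupled device with a periodic pore, places particles
randomly rather than from a pre-equilibrated liquid, and treats the
nominal molarity as an ion/water ratio (the accessible-volume molarity
inside the pore is smaller because the wall excludes a shell).  Passing
tests therefore demonstrate the interaction model, samplers and analyses
on systems *constructed to the stated conditions*; they do not
demonstrate force-field accuracy against experimental ion distributions,
nor convergence at the full 8 ns schedule.

## Numerical choices

* SHAKE/RATTLE tolerance 1e-10 (relative, squared distances), 500
  iteration cap; collinear reference geometry raises.
* Overlap guard: any non-bonded pair below 0.1 Å aborts the force call.
* Ewald accuracy target 1e-8 on the Gaussian tails (α = 3.5/r_max,
  k-cutoff from the same tolerance).
* MC wall gap 0.2 Å; Metropolis on pre-drawn uniforms.
* Degenerate inputs: empty systems return zero energy and no forces;
  zero production steps return an empty but fully annotated trajectory;
  an all-zero density profile yields a flagged no-peak report rather
  than an error.
* Peak tolerance in validation: one bin width (0.5 Å at the scaled-run
  binning).

## Known limitations

* The reaction-field route treats the heterogeneous pore interior as a
  homogeneous dielectric beyond the cutoff; quantitative long-range
  screening is better served by the Ewald route at higher cost.
* The implicit-solvent mode has no hydration shells, so its contact
  peaks sit at the bare Steele minimum (~2.8 Å for Na+) rather than the
  explicit-water 1.5 Å; it is a structure-trend tool, not a
  peak-position tool.
* Desk-scale explicit runs (~100 ps) carry visible sampling noise.  The
  counterion contact peak is robust across seeds; the coion layer is
  broader (spanning roughly 3-5 Å from the wall with its maximum near
  4 Å under the default scaled conditions), its exact maximum bin moves
  with the degree of counterion condensation, and mid-pore bulk
  fluctuations of a dozen coions can transiently rival it for the
  global maximum.  Full-length runs are needed before reading the
  coion global maximum alone.
* No pressure coupling, applied fields, or ionic-current observables.
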