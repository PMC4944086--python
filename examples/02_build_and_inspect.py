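"""Build an electroneutral confined electrolyte and inspect it.

A 2 M NaCl filling of the 3 nm-radius pore: the builder chooses ion
counts from the molarity/water ratio, adds one Na+ per frozen -1 e wall
charge so the whole cell is neutral, and packs everything by rejection
sampling.  The same spec (including seed) always rebuilds the identical
system.
"""

from nanopore_edl import BuildSpec, build_system

spec = BuildSpec(concentration=2.0, n_water=1045, n_wall_charges=8, rng_seed=1)
config = build_system(spec)

print(f"pore radius {config.geometry.r_n} Å, periodic length {config.geometry.l_z} Å")
print(f"mobile sites: {config.n_particles}  (Na+ {config.count('Na+')}, "
      f"Cl- {config.count('Cl-')}, waters {config.count('O')})")
print(f"frozen wall charges: {config.n_wall_charges}")
print(f"total charge: {config.total_charge} e   (exact neutrality by construction)")
print(f"surface charge density: {config.sigma_s:.4f} C/m^2")
print(f"largest mobile radius: {config.radii.max():.2f} Å  (< {config.geometry.r_n} Å)")
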