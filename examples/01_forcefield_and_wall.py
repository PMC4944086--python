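"""Mixed-pair LJ parameters and the Steele wall minimum.

Builds the default force field, applies Lorentz-Berthelot mixing to the
pure pairs, and scans the 10-4-3 wall potential for Na+ in a 3 nm-radius
pore.  The printed mixed rows are the table a practitioner would quote;
the wall scan shows where an ion prefers to sit before electrostatics.
"""

import dataclasses

import numpy as np

from nanopore_edl import combine_lorentz_berthelot, default_forcefield

ff = default_forcefield()

print("Lorentz-Berthelot mixed pairs (sigma Å, epsilon kJ/mol):")
for a, b in [("Na+", "Cl-"), ("Na+", "O"), ("Cl-", "O")]:
    p = combine_lorentz_berthelot(ff[a], ff[b])
    print(f"  {a:4s}-{b:4s}  sigma={p.sigma_ij:6.3f}  epsilon={p.epsilon_ij:6.4f}")

wall = dataclasses.replace(ff.wall, r_n=30.0)
r = np.arange(1e-3, 30.0 - 1e-3, 1e-3)
u = wall.steele_energy(r, ff["Na+"])
i = int(u.argmin())
print(f"\nSteele wall for Na+ (pore radius 30 Å):")
print(f"  minimum {u[i]:.3f} kJ/mol at {30.0 - r[i]:.3f} Å from the wall")
print("  -> the bare wall holds an ion a few Å off the surface; wall charges pull it closer.")
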