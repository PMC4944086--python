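# Default interaction parameters for NaCl solution confined in a charged
# silica-like cylindrical nanopore.
#
# Pure-pair Lennard-Jones parameters (sigma in Å, epsilon in kJ/mol);
# mixed pairs follow the Lorentz-Berthelot combining rules.  Water is the
# rigid three-site SPC/E model: the single LJ site sits on oxygen and the
# hydrogens carry charge only.

[species.O]
mass = 15.9994
charge = -0.8476
sigma = 3.169
epsilon = 0.6502

[species.H]
mass = 1.008
charge = 0.4238
sigma = 0.0
epsilon = 0.0

[species.Na+]
mass = 22.98977
charge = 1.0
sigma = 2.583
epsilon = 0.4184

[species.Cl-]
mass = 35.453
charge = -1.0
sigma = 4.401
epsilon = 0.4184

# non-interacting tracer for analytic test fixtures
[species.TRACER]
mass = 1.0
charge = 0.0
sigma = 0.0
epsilon = 0.0

# frozen elementary wall charge (never integrated; Coulomb only)
[species.WALLQ]
mass = 0.0
charge = -1.0
sigma = 0.0
epsilon = 0.0

[water]
r_oh = 1.0
angle_hoh = 109.47

# Steele 10-4-3 wall: interlayer spacing Delta (Å), solid density rho_w
# (nm^-3), and bulk-silica LJ parameters sigma_w (Å), epsilon_w/kB (K).
[wall]
delta = 2.709
rho_w = 42.76
sigma_w = 3.0
epsilon_w_over_kb = 230.0
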