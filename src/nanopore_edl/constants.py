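"""Physical constants and the internal unit system.

Internal units: length Å, mass g/mol, energy kJ/mol, time fs, charge e.
Velocities are therefore Å/fs and forces kJ/(mol·Å).  Two conversion
factors glue kinetics to energetics:

* ``ACCEL_FACTOR`` — multiply (force/mass) in kJ/(mol·Å·g/mol) to get Å/fs².
* ``KINETIC_FACTOR`` — multiply ``0.5*m*v**2`` (g/mol · Å²/fs²) to get kJ/mol.
"""

# Boltzmann constant, kJ/(mol K)
KB = 0.008314462618

# Coulomb constant e^2/(4 pi eps0), kJ Å / (mol e^2)
COULOMB_KJ = 1389.35458

# Coulomb constant in volts: e/(4 pi eps0), V Å / e
COULOMB_VOLT = 14.399645

# Faraday constant, C/mol
FARADAY = 96485.33212

AVOGADRO = 6.02214076e23

# elementary charge, C
E_CHARGE = 1.602176634e-19

# molarity of pure liquid water at ambient conditions, mol/L
WATER_MOLARITY = 55.345

# relative permittivity of the implicit solvent in the primitive-model mode
WATER_EPS_R = 78.4

# unit-system glue (see module docstring)
ACCEL_FACTOR = 1.0e-4
KINETIC_FACTOR = 1.0e4

# Å^3 -> litres
A3_TO_L = 1.0e-27
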