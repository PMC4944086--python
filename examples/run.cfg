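# Fast implicit-solvent run in the charged 3 nm pore (about a minute).
# Keys not listed keep their defaults (see nanopore_edl.config.RunConfig).
concentration = 1.3
n_water = 1045
n_wall_charges = 8
mode = 'mc_primitive'
n_equil_steps = 50000
n_prod_steps = 500000
sample_interval = 1000
bin_width = 0.5
seed = 1
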