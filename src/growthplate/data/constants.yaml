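# Physiological constants for the rat proximal tibia growth plate.
fixture_version: 1
h_max_f_um: 35.0        # fully hypertrophic chondrocyte height, physiological
columns: 20             # chondrocyte columns across the domain
column_spacing_um: 40.0 # lateral separation between columns
domain_side_um: 800.0   # square analysis domain edge length
duration_days: 23.0     # validation simulation span
sigma_n_f_MPa: 0.0      # physiological baseline axial stress (load is expressed as a difference from it)
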