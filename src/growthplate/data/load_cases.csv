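delta_sigma_n_MPa,reserve_um,proliferative_um,hypertrophic_um,proliferative_cells,hypertrophic_cells,G_stokes_um_per_day,h_max_um,delta_t_days
0.1,13.9,288,175,23,7,228.7,36.22,0.158
0.0,12.3,264,162,22,6,217.0,35.00,0.161
-0.1,11.9,269,129,22,5,183.4,35.94,0.196
-0.2,10.9,242,123,18,5,163.8,34.30,0.209
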