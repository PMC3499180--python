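tissue_name,youngs_modulus_MPa,poisson_ratio
trabecular_bone,2000,0.30
reserve,0.48,0.07
proliferative,0.25,0.13
hypertrophic,0.27,0.13
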