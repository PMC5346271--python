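model_id,body_mass_g,Qc_mL_per_s,Qw_mL_per_s,assimilation_factor,provenance
7C,0.65,9.5e-4,2.57e-3,0.8,assumed (adult female zebrafish scale; ventilation:cardiac ratio ~2.7; gill transfer efficiency assumed)
6C,0.65,9.5e-4,2.57e-3,,body-centric values shared with the 7C fixture
1C,0.65,,2.57e-3,,respiratory flow shared with the 7C fixture
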