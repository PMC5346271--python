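compartment,volume_mL,flow_mL_per_s,f_lipid,f_water,provenance
body,0.65,,0.027544615384615383,0.8210984615384616,volume-weighted whole-body composition of the 7C fixture (blood as water; exact)
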