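compartment,volume_mL,flow_mL_per_s,f_lipid,f_water,provenance
arterial,0.011,,,,shared with 7C fixture
venous,0.022,,,,shared with 7C fixture
brain,0.0065,5.70e-5,0.08,0.78,shared with 7C fixture
gonads,0.052,1.90e-5,0.10,0.75,shared with 7C fixture
liver,0.0078,2.85e-5,0.05,0.75,shared with 7C fixture
other,0.5507,8.455e-4,0.02141637915380425,0.8185836208461957,volume-weighted merge of the 7C rpt+ppt rows (exact)
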