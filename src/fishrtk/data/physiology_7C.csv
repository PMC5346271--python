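compartment,volume_mL,flow_mL_per_s,f_lipid,f_water,provenance
arterial,0.011,,,,assumed (blood ~5% of body volume; 1:2 arterial:venous split)
venous,0.022,,,,assumed (blood ~5% of body volume; 1:2 arterial:venous split)
brain,0.0065,5.70e-5,0.08,0.78,assumed (zebrafish literature structure; lipid-rich neural tissue)
gonads,0.052,1.90e-5,0.10,0.75,assumed (mature female ovary; lipid-rich; poorly perfused)
liver,0.0078,2.85e-5,0.05,0.75,assumed (zebrafish literature structure)
rpt,0.039,2.28e-4,0.04,0.80,assumed (richly perfused viscera)
ppt,0.5117,6.175e-4,0.02,0.82,assumed (muscle/skin/skeleton remainder)
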