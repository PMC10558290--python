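name,western_um,gfp_um,mass_spec_um
Act1,13.2,,14.8
Abp1,5.15,5.55,
Crn1,1.40,1.56,
Cap1/2,1.46,1.62,
Sac6,1.21,7.71,1.40
Srv2,2.88,,2.69
Twf1,1.10,0.53,0.65
Scp1,0.85,,1.02
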