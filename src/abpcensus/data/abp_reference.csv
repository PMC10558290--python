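name,common_name,mw_kda,abundance_ng_per_ug,abundance_sd,n_blots,cellular_conc_um,cellular_conc_sd,molecules_per_cell,pct_free_cytosol,pct_free_cytosol_sd,cytosolic_conc_um,cytosolic_conc_sd,binds_f_actin,binds_g_actin,oligomer_n,method
Act1,Actin,41.8,7.99,1.48,11,13.2,2.44,217000,,,,,False,False,1,western
Tpm1,Tropomyosin,23.5,4.22,1.08,6,12.4,3.16,203000,89,8,11,0.98,True,False,1,western
Pfy1,Profilin,13.6,1.54,0.27,,7.73,1.38,127000,,,,,False,True,1,gfp
Cof1,Cofilin,16.0,1.76,0.78,3,7.58,3.36,125000,,,,,True,True,1,western
Abp1,Actin-binding protein 1,65.6,4.91,0.79,2,5.15,0.83,84700,61,11,3.2,0.60,True,False,1,western
Srv2,Cyclase-associated protein,57.6,2.41,0.36,5,2.88,0.43,47400,78,9,2.2,0.26,True,True,6,western
Abp140,Actin-binding protein 140,71.4,2.94,,,2.83,0.60,46500,87,8,2.5,0.23,True,False,1,gfp
Tpm2,Tropomyosin,19.1,0.70,,,2.54,,41700,91,8,2.3,0.20,True,False,1,ratio
Aip1,Actin-interacting protein 1,67.4,1.81,0.02,2,1.85,0.02,24000,82,7,1.5,0.13,True,False,1,western
Cap1/2,Capping protein (alpha/beta heterodimer),64.3,1.43,0.53,7,1.46,0.54,51200,67,8,0.9,0.15,True,False,2,western
Crn1,Coronin,72.6,1.48,0.28,6,1.40,0.27,23100,63,11,0.9,0.15,True,False,1,western
Sac6,Fimbrin,71.8,1.26,0.02,2,1.21,0.02,19900,80,8,1.0,0.10,True,False,1,western
Twf1,Twinfilin,37.1,0.59,0.19,8,1.10,0.35,18000,71,12,0.8,0.13,True,True,1,western
Arp2,Actin-related protein 2,44.1,0.63,0.20,4,0.98,0.31,16200,81,7,0.8,0.07,True,False,1,western
Scp1,Calponin/transgelin,22.8,0.28,0.05,3,0.85,0.15,13900,74,13,0.6,0.11,True,False,1,western
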