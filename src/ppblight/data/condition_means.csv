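# Per-condition means transcribed from the published study's summary table:
# end-of-reaction biomass and acetate concentrations and specific growth rates
# for the nine incident infrared irradiance conditions. Acetate below the
# detection limit is entered as 0.0.
irradiance_W_m2,biomass_gVSS_L,biomass_sd,acetate_mmol_L,acetate_sd,mu_h,mu_sd,acetate_bdl
0,0.09,0.02,3.79,0.68,0.03,0.03,false
3,0.15,0.01,3.28,0.36,0.01,0.01,false
7,0.75,0.05,3.00,1.33,0.01,0.01,false
15,0.61,0.06,2.34,2.02,0.02,0.01,false
30,1.28,0.02,1.37,0.49,0.01,0.01,false
87,2.04,0.11,0.27,0.05,0.02,0.00,false
175,2.37,0.06,0.04,0.10,0.10,0.01,false
264,2.65,0.04,0.05,0.06,0.18,0.03,false
350,2.94,0.48,0.00,0.00,0.22,0.05,true
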