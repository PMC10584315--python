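scheme,amount_mm,cycle_days,n_events,yield_t_ha,biomass_t_ha,wue_kg_m3,et_mm
A1,90,5,12,27.89,7.13,10.50,260
A2,90,7,9,28.00,6.79,10.71,254
A3,90,10,6,28.30,6.56,11.37,242
A4,120,5,12,30.25,7.70,10.65,279
A5,120,7,9,30.45,7.63,10.86,273
A6,120,10,6,31.00,7.22,11.73,258
A7,150,5,12,34.33,8.62,11.16,303
A8,150,7,9,33.50,8.34,11.22,291
A9,150,10,6,33.03,7.61,12.01,269
A10,180,5,12,43.40,9.62,12.97,332
A11,180,7,9,40.88,9.16,12.81,314
A12,180,10,6,34.47,8.1,11.99,281
A13,210,5,12,36.99,9.09,11.55,318
A14,210,7,9,37.28,8.77,12.12,301
A15,210,10,6,34.26,7.92,12.14,276
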