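scheme,quota_mm,cycle_days,n_events,yield_t_ha,biomass_t_ha,wue_kg_m3,et_mm
A16,10,5,12,30.25,7.70,10.65,279
A17,10,7,9,28,6.79,10.61,256
A18,10,10,6,25.28,5.63,11.04,223
A19,13,5,12,34.33,8.62,11.16,303
A20,13,7,9,30.45,7.52,10.86,273
A21,13,10,6,27.03,6.22,11.14,236
A22,18,5,12,43.4,9.62,12.97,332
A23,18,7,9,34.69,8.49,11.47,295
A24,18,10,6,30.00,7.02,11.58,253
A25,20,5,12,49.76,10.53,13.74,358
A26,20,7,9,46.77,9.28,15.74,300
A27,20,10,6,32.62,7.81,11.95,267
A28,24,5,12,44.01,9.71,13.01,333
A29,24,7,9,38.40,8.98,12.18,311
A30,24,10,6,30.81,7.22,11.69,258
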