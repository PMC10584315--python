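top_cm,bottom_cm,theta_wp,theta_fc,theta_sat,bulk_density,clay_pct,silt_pct,sand_pct
0,20,0.10,0.19,0.32,1.41,21.28,5.72,73.00
20,40,0.10,0.20,0.35,1.38,22.89,4.21,72.90
40,60,0.12,0.23,0.38,1.36,22.29,4.01,73.70
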