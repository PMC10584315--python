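scheme,scenario,amount_mm,quota_mm,cycle_days,n_events,total_m3_ha
A1,I,90,,5,12,900
A2,I,90,,7,9,900
A3,I,90,,10,6,900
A4,I,120,,5,12,1200
A5,I,120,,7,9,1200
A6,I,120,,10,6,1200
A7,I,150,,5,12,1500
A8,I,150,,7,9,1500
A9,I,150,,10,6,1500
A10,I,180,,5,12,1800
A11,I,180,,7,9,1800
A12,I,180,,10,6,1800
A13,I,210,,5,12,2100
A14,I,210,,7,9,2100
A15,I,210,,10,6,2100
A16,II,,10,5,12,1200
A17,II,,10,7,9,900
A18,II,,10,10,6,600
A19,II,,13,5,12,1560
A20,II,,13,7,9,1170
A21,II,,13,10,6,780
A22,II,,18,5,12,2160
A23,II,,18,7,9,1620
A24,II,,18,10,6,1080
A25,II,,20,5,12,2400
A26,II,,20,7,9,1800
A27,II,,20,10,6,1200
A28,II,,24,5,12,2880
A29,II,,24,7,9,2160
A30,II,,24,10,6,1440
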