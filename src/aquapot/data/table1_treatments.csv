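year,treatment,sowing_date,irrigation_start,irrigation_end,n_irrigations,amount_mm
2019,T1,2019-04-30,2019-05-18,2019-08-26,9,90
2019,T2,2019-04-30,2019-05-18,2019-08-26,9,150
2019,T3,2019-04-30,2019-05-18,2019-08-26,9,210
2020,T4,2020-05-04,2020-05-18,2020-08-26,10,90
2020,T5,2020-05-04,2020-05-18,2020-08-26,10,135
2020,T6,2020-05-04,2020-05-18,2020-08-26,10,180
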