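year,stage,window_start,window_end,pct,n_events
2019,bud,05-10,06-05,9,1
2019,seedling,06-06,06-25,16,2
2019,tuber_formation,06-26,07-25,25,3
2019,tuber_growth,07-26,08-20,50,3
2019,starch_accumulation,08-21,09-27,0,0
2020,bud,05-10,06-05,8.85,1
2020,seedling,06-06,06-25,17.7,2
2020,tuber_formation,06-26,07-25,31.86,3
2020,tuber_growth,07-26,08-20,32.74,3
2020,starch_accumulation,08-21,09-27,8.85,1
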