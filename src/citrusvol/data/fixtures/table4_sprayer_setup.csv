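orchard_id,date,pest,pressure_bar,forward_speed_kmh,air_volume_m3h,nozzles_vc,nozzles_va
P1,2016-05-27,CRS (first generation),8,1.32,55342.15,38,30
P1,2016-07-27,CRS (second generation) and TSM,8,1.32,55342.15,38,30
P1,2016-10-11,TSM,8,1.32,55342.15,38,30
P2,2016-05-26,CRS (first generation),8,1.32,55342.15,38,28
P2,2016-06-22,TSM,8,1.73,55342.15,38,30
P2,2016-08-09,CRS (second generation) and TSM,8,1.32,55342.15,38,28
P2,2016-09-09,TSM,8,1.73,55342.15,38,30
P3,2016-06-09,CRS (first generation),13,1.75,101248.29,26,18
P4,2016-05-31,CRS (first generation),9,1.92,54828.19,36,14
P5,2016-05-31,CRS (first generation),9,1.92,54828.19,34,18
P6,2016-06-16,CRS (first generation),8,1.53,89268.43,26,22
P6,2016-08-12,CRS (second generation),8,1.48,89268.43,26,22
P7,2016-06-14,CRS (first generation),8,1.53,89268.43,26,26
P7,2016-08-11,CRS (second generation),8,1.48,89268.43,26,26
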