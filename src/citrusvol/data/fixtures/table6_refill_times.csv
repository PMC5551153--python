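orchard_id,date,tank_capacity,tanks_vc,tanks_va,savings_h_1ha,savings_h_10ha,savings_h_100ha
P1,2016-05-27,1500,4,3,0.67,7.33,73.33
P1,2016-07-27,1500,4,3,0.67,7.33,73.33
P1,2016-10-11,1500,4,3,0.67,7.33,73.33
P2,2016-05-26,1500,3,2,0.67,6.67,62.66
P2,2016-06-22,1500,3,2,0.67,3.33,32.66
P2,2016-08-09,1500,3,2,0.67,6.67,62.66
P2,2016-09-09,1500,3,2,0.67,3.33,32.66
P3,2016-06-09,2000,2,2,0,3.33,32.66
P4,2016-05-31,2000,4,2,1.33,14,143.33
P5,2016-05-31,2000,4,1,2,16.67,166
P6,2016-06-16,3000,2,1,0.67,1.33,14.66
P6,2016-08-12,3000,2,1,0.67,4,37.33
P7,2016-06-14,3000,2,2,0,0.67,8.66
P7,2016-08-11,3000,2,2,0,0.67,9.33
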