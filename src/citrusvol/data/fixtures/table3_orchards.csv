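orchard_id,cultivar,sp_row,sp_tree,h,d_across,d_along,vt1_printed
P1,Clemenules,6,3,2.51,4.33,3.08,17.53
P2,Oronules,7,2,2.12,4.26,2.30,10.88
P3,Clemenules,6.8,5,2.15,3.39,3.34,12.75
P4,Clemenules,5.5,5,2.38,4.28,4.57,24.37
P5,Clemenules,6,2,1.99,2.93,1.96,5.98
P6,Clemenules,6.5,2.5,2.47,3.90,2.60,13.11
P7,Clemenules,6.5,3.5,2.45,4.84,3.70,22.97
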