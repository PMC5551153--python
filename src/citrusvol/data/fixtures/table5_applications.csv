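orchard_id,date,pest,ingredient,concentration_pct,vc,va,reduction_printed,savings_printed
P1,2016-05-27,CRS (first generation),chlorpyrifos,0.20,4905,3255,33.64,3.30
P1,2016-05-27,CRS (first generation),pyriproxyfen,0.05,4905,3255,33.64,0.83
P1,2016-05-27,CRS (first generation),abamectin,0.04,4905,3255,33.64,0.66
P1,2016-05-27,CRS (first generation),spirodiclofen,0.02,4905,3255,33.64,0.33
P1,2016-07-27,CRS (second generation) and TSM,abamectin,0.10,4905,3255,33.64,1.65
P1,2016-07-27,CRS (second generation) and TSM,spirotetramat,0.04,4905,3255,33.64,0.66
P1,2016-07-27,CRS (second generation) and TSM,spirodiclofen,0.02,4905,3255,33.64,0.33
P1,2016-10-11,TSM,abamectin,0.10,4905,3255,33.64,1.65
P2,2016-05-26,CRS (first generation),chlorpyrifos,0.20,4204,2800,33.39,2.81
P2,2016-05-26,CRS (first generation),etoxazole,0.05,4204,2800,33.39,0.70
P2,2016-05-26,CRS (first generation),pyriproxyfen,0.05,4204,2800,33.39,0.70
P2,2016-05-26,CRS (first generation),abamectin,0.04,4204,2800,33.39,0.56
P2,2016-06-22,TSM,abamectin,0.10,3215,2476,22.98,0.74
P2,2016-06-22,TSM,spirodiclofen,0.02,3215,2476,22.98,0.15
P2,2016-08-09,CRS (second generation) and TSM,abamectin,0.10,4204,2800,33.39,1.40
P2,2016-08-09,CRS (second generation) and TSM,spirotetramat,0.04,4204,2800,33.39,0.56
P2,2016-08-09,CRS (second generation) and TSM,tetrazine,0.02,4204,2800,33.39,0.28
P2,2016-09-09,TSM,abamectin,0.10,3215,2476,22.28,0.74
P2,2016-09-09,TSM,spirodiclofen,0.02,3215,2476,22.28,0.15
P3,2016-06-09,CRS (first generation),abamectin,0.04,3264,2294,29.70,0.39
P3,2016-06-09,CRS (first generation),spirotetramat,0.02,3264,2294,29.70,0.19
P3,2016-06-09,CRS (first generation),clofentezine,0.01,3264,2294,29.70,0.10
P4,2016-05-31,CRS (first generation),spirotetramat,0.04,7311,3011,58.82,1.72
P5,2016-05-31,CRS (first generation),chlorpyrifos,0.20,6702,1737,74.08,9.93
P5,2016-05-31,CRS (first generation),pyriproxyfen,0.08,6702,1737,74.08,3.97
P5,2016-05-31,CRS (first generation),spirodiclofen,0.02,6702,1737,74.08,0.99
P6,2016-06-13,CRS (first generation),chlorpyrifos,0.27,3200,2535,20.81,1.80
P6,2016-06-13,CRS (first generation),abamectin,0.13,3200,2535,20.81,0.86
P6,2016-06-13,CRS (first generation),pyriproxyfen,0.07,3200,2535,20.81,0.47
P6,2016-06-13,CRS (first generation),clofentezine,0.02,3200,2535,20.81,0.13
P6,2016-08-12,CRS (second generation),spirotetramat,0.04,3318,1628,20.81,0.68
P7,2016-06-14,CRS (first generation),chlorpyrifos,0.27,3468,3065,11.61,1.09
P7,2016-06-14,CRS (first generation),abamectin,0.13,3468,3065,11.61,0.52
P7,2016-06-14,CRS (first generation),pyriproxyfen,0.07,3468,3065,11.61,0.28
P7,2016-06-14,CRS (first generation),clofentezine,0.02,3468,3065,11.61,0.08
P7,2016-08-11,CRS (second generation),spirotetramat,0.04,3595,3177,11.61,0.17
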