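cultivar,batch,origin,temperature_c,ethylene_ul_l,f0_mean,f0_sd,eth,eth_se,f_fix,f_fix_se,r2adj_pct
Kent,1,Peru,20,0,33.0,3.9,,,,,
Kent,1,Peru,20,115,,,,,,,
Keitt,2,Brazil,"10,17,24,30",0,61.7,16.8,1.52,0.03,12.7,0.3,94.9
Keitt,3,Spain,variable,0,43.8,4.6,0.83,0.05,3.7,0.7,
Keitt,4,Puerto Rico,"12,16,20,24",0,50.4,8.7,0.80,0.03,23.7,0.3,86.0
Keitt,5,Israel,variable,0,43.1,6.2,0.63,0.02,18.2,0.3,89.1
Keitt,5,Israel,variable,100,,,5.62,0.27,,,
Keitt,6,Brazil,variable,0,39.1,6.5,1.01,0.06,13.5,0.8,90.0
Keitt,6,Brazil,variable,100,,,1.25,0.09,,,
Keitt,7,Brazil,variable,0,35.9,4.4,1.97,0.12,16.4,0.4,89.4
Keitt,7,Brazil,variable,100,,,2.54,0.15,,,
Keitt,8,Spain,variable,0,82.4,1.3,1.05,0.03,17.8,0.4,94.8
Keitt,8,Spain,variable,0,66.9,1.4,,,,,
Keitt,8,Spain,variable,10,86.2,1.4,1.83,0.06,,,
Keitt,8,Spain,variable,10,69.3,1.6,,,,,
Keitt,8,Spain,variable,50,86.0,1.4,1.89,0.07,,,
Keitt,8,Spain,variable,50,74.7,1.7,,,,,
Keitt,8,Spain,variable,100,87.0,1.5,2.06,0.07,,,
Keitt,8,Spain,variable,100,72.8,1.7,,,,,
Keitt,9,unknown,20,0,33.9,11.1,2.23,0.36,7.6,0.4,87.4
Keitt,9,unknown,20,3,,,5.30,0.81,,,
Keitt,9,unknown,20,100,,,7.89,0.84,,,
Kent,10,Brazil,"10,17,24,30",0,36.3,12.5,0.48,0.13,6.9,0.5,95.0
Kent,11,Mali,"12,16,20,24",0,34.2,14.4,0.76,0.18,22.6,0.5,
Kent,12,Ivory Coast,20,0,42.8,2.6,0.57,0.14,8.0,0.8,
Kent,12,Ivory Coast,20,10,,,0.70,0.16,,,
Kent,12,Ivory Coast,20,100,,,0.64,0.15,,,
Kent,13,Mali,20,0,27.0,3.4,0.49,0.14,7.6,0.7,
Kent,13,Mali,20,10,,,0.77,0.22,,,
Kent,13,Mali,20,100,,,0.85,0.23,,,
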