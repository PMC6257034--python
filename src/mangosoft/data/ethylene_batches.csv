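cultivar,batch,sub_batch,origin,dur1_d,temp1_c,dur2_d,temp2_c,f0_init_fi,ethylene_ul_l,eth,ef
Keitt,5,5a,Israel,2.8,17.8,3.2,13.5,37.4,0,0.63,0.013
Keitt,5,5b,Israel,2.8,17.8,3.2,13.5,,100,5.62,0.117
Keitt,5,5c,Israel,3.2,19.5,10.8,13.0,41.3,0,0.63,0.010
Keitt,5,5d,Israel,3.2,19.5,10.8,13.0,,100,5.62,0.091
Keitt,5,5e,Israel,2.8,16.6,10.2,19.9,44.4,0,0.63,0.032
Keitt,5,5f,Israel,2.8,16.6,10.2,19.9,,100,5.62,0.286
Keitt,5,5g,Israel,3.2,19.8,9.8,22.1,52.3,0,0.63,0.056
Keitt,5,5h,Israel,3.2,19.8,9.8,22.1,,100,5.62,0.499
Keitt,6,6a,Brazil,6,20.0,4,20.0,33.8,0,1.01,0.062
Keitt,6,6b,Brazil,6,20.0,4,20.0,,100,1.25,0.077
Keitt,6,6c,Brazil,6,16.0,4,20.0,43.6,0,1.01,0.035
Keitt,6,6d,Brazil,6,16.0,4,20.0,,100,1.25,0.043
Keitt,7,7a,Brazil,4,18.0,6,16.0,39.0,0,1.97,0.056
Keitt,7,7b,Brazil,4,18.0,6,16.0,,100,2.54,0.073
Keitt,7,7c,Brazil,4,16.0,6,20.0,32.0,0,1.97,0.083
Keitt,7,7d,Brazil,4,16.0,6,20.0,,100,2.54,0.107
Keitt,8,8a,Spain,10,20,,,82.4,0,1.05,0.065
Keitt,8,8b,Spain,10,20,,,86.2,10,1.83,0.113
Keitt,8,8c,Spain,10,20,,,86.0,50,1.89,0.117
Keitt,8,8d,Spain,10,20,,,87.0,100,2.06,0.127
Keitt,8,8e,Spain,10,20,,,66.9,0,1.05,0.065
Keitt,8,8f,Spain,10,20,,,69.3,10,1.83,0.113
Keitt,8,8g,Spain,10,20,,,74.7,50,1.89,0.117
Keitt,8,8h,Spain,10,20,,,72.8,100,2.06,0.127
Keitt,9,9a,unknown,16,20,,,,0,2.23,0.138
Keitt,9,9b,unknown,16,20,,,33.9,3,5.30,0.327
Keitt,9,9c,unknown,16,20,,,,100,7.89,0.487
Kent,12,12a,Ivory Coast,15,20,,,,0,0.57,0.332
Kent,12,12b,Ivory Coast,15,20,,,42.8,10,0.70,0.408
Kent,12,12c,Ivory Coast,15,20,,,,100,0.64,0.373
Kent,13,13a,Mali,15,20,,,,0,0.49,0.285
Kent,13,13b,Mali,15,20,,,27.0,10,0.77,0.448
Kent,13,13c,Mali,15,20,,,,100,0.85,0.495
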