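roi_id,description,t1_dl,t1_routine,t2_dl,t2_routine,pd_dl,pd_routine
1,WMH,1019.68,1052.20,100.84,112.9,80.70,79.16
2,WMH,1034.41,1052.78,96.32,96.71,75.21,77.09
3,WMH,955.68,1013.20,94.78,104.52,70.77,72.97
4,infarct,1217.30,1398.16,126.53,149.71,80.00,81.26
5,encephalomalacia,3597.26,3683.45,310.67,276.99,102.83,106.59
6,WMH,1088.41,1214.51,109.50,121.23,82.11,84.70
7,infarct,1832.00,1679.00,136.10,133.80,90.50,90.90
8,encephalomalacia,3719.04,3892.54,292.16,272.32,101.31,104.98
9,WMH,1734.53,1517.03,163.45,182.01,85.14,86.37
10,WMH,1171.00,1238.00,110.60,124.70,80.70,81.10
11,encephalomalacia,3666.00,3469.00,350.20,295.80,107.80,106.30
12,WMH,1253.00,1285.00,113.20,105.20,78.70,83.00
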