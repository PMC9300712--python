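dose_g_per_L,pH,temp_C,conc_mg_per_L,removal_pct,removal_reg_pct,removal_ann_pct,split
0.7,6,35,0.7,88.3,89.9,88.6,train
0.4,4,40,0.4,59.4,60.6,59.3,train
0.7,6,35,0.7,89.4,91.9,89.7,train
1.0,4,30,1.0,64.2,67.7,64.2,train
1.0,4,40,1.0,63.8,65.6,63.2,train
1.0,8,30,0.4,53.8,58.7,53.4,train
0.7,10,35,0.7,58.9,57.1,57.7,train
1.3,6,35,0.7,76.4,73.3,75.9,train
0.7,6,25,0.7,63.7,58.5,62.8,train
0.7,6,35,0.7,92.6,89.9,93.1,train
1.0,8,40,0.4,78.8,77.9,78.3,train
0.7,6,35,0.7,91.1,88.3,92.3,train
0.7,6,35,0.7,90.4,91.1,89.8,train
0.1,6,35,0.7,75.4,74.3,74.5,train
0.4,8,30,0.4,59.9,57.2,59.2,train
0.4,4,40,1.0,67.8,66.2,68.2,train
0.7,6,45,0.7,71.9,73.5,71.7,train
0.4,8,30,1.0,69.9,72.6,68.8,train
0.7,6,35,0.7,90.9,89.8,91.2,train
0.7,6,35,1.3,94.8,91.8,96.1,train
0.7,6,35,0.7,87.1,89.7,87.0,train
0.4,4,30,0.4,59.3,61.6,59.1,train
1.0,8,30,1.0,66.8,66.8,65.2,train
1.0,4,40,0.4,64.7,68.4,65.3,train
0.4,8,40,1.0,83.4,84.4,84.1,test
1.0,8,40,1.0,80.6,81.7,80.1,test
0.7,2,35,0.7,46.2,43.4,47.8,test
0.4,4,30,1.0,69.2,71.3,70.1,test
0.4,8,40,0.4,75.4,75.4,75.2,test
0.7,6,35,0.1,79.8,78.3,78.4,test
1.0,4,30,0.4,63.1,66.2,63.4,test
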