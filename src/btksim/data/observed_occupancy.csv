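dose_mg,n_obs,pct_gt90
80,8,50
120,12,67
160,7,43
200,12,100
240,7,100
280,4,75
320,4,100
420,119,77
440,7,100
520,4,100
560,49,90
600,8,50
640,13,85
720,4,100
800,4,75
840,40,92
880,4,100
960,1,100
1000,4,75
1060,5,100
1400,4,50
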