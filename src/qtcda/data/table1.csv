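name,p,p_lo,p_hi,dqtc,dqtc_lo,dqtc_hi
Amisulpride,0.804,0.153,0.989,14.10,7.71,20.45
Haloperidol,0.703,0.510,0.844,1.69,-0.23,3.64
Olanzapine,0.711,0.415,0.896,4.29,1.91,6.68
Quetiapine,0.791,0.355,0.963,3.43,0.94,6.00
Risperidone,0.611,0.359,0.814,4.77,2.68,6.87
Ziprasidone,0.743,0.324,0.945,9.70,7.43,12.04
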