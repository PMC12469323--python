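interval,km,theoretical_variable,actual_variable
1.0,0.001,39,32
1.0,0.002,30,24
1.0,0.003,27,20
1.0,0.004,26,17
1.0,0.005,24,15
0.1,0.001,30,28
0.1,0.002,21,20
0.1,0.003,18,17
0.1,0.004,17,16
0.1,0.005,15,13
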