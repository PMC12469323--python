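interval,km,theoretical_variable,actual_variable
1.0,0.001,39,37
1.0,0.002,30,28
1.0,0.003,27,25
1.0,0.004,26,24
1.0,0.005,24,22
0.1,0.001,30,30
0.1,0.002,21,21
0.1,0.003,18,18
0.1,0.004,17,17
0.1,0.005,15,15
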