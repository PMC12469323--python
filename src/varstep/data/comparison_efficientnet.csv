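interval,km,theoretical_variable,actual_variable
1.0,0.001,39,35
1.0,0.002,30,29
1.0,0.003,27,21
1.0,0.004,26,15
1.0,0.005,24,13
0.1,0.001,30,28
0.1,0.002,21,19
0.1,0.003,18,14
0.1,0.004,17,13
0.1,0.005,15,11
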