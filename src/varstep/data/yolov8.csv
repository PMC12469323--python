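lr,accuracy
1e-05,0.5133
0.0001,0.8230
0.0004,0.8723
0.0006,0.8849
0.001,0.8731
0.0015,0.8495
0.006,0.8849
0.01,0.8407
0.02,0.4424
0.03,0.4425
0.04,0.3716
0.05,0.2035
0.06,0.1947
0.07,0.1593
0.1,0.2212
0.2,0.2310
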