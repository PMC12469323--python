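lr,accuracy
1e-05,0.7651
0.0001,0.9800
0.0005,0.9613
0.001,0.9750
0.0015,0.9572
0.002,0.9372
0.006,0.9525
0.01,0.9200
0.02,0.8725
0.03,0.8875
0.04,0.8025
0.05,0.7875
0.06,0.7400
0.1,0.7175
0.2,0.6900
0.3,0.4950
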