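lr,accuracy
1e-05,0.4847
0.0001,0.8045
0.001,0.9226
0.006,0.9572
0.01,0.9654
0.015,0.9674
0.02,0.9532
0.03,0.9511
0.04,0.9043
0.05,0.8371
0.06,0.7862
0.07,0.8391
0.08,0.8737
0.09,0.8656
0.1,0.8534
0.2,0.8310
0.3,0.7984
0.4,0.8004
0.5,0.8106
0.6,0.7739
0.7,0.7658
0.8,0.7515
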