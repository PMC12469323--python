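lr,accuracy
1e-05,0.4745
0.0001,0.8635
0.001,0.9348
0.006,0.9613
0.01,0.9633
0.015,0.9572
0.02,0.9572
0.03,0.9185
0.04,0.7902
0.05,0.7760
0.06,0.7108
0.1,0.6986
0.2,0.5621
0.3,0.5988
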