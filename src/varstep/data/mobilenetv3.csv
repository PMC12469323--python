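lr,accuracy
1e-05,0.5040
0.0001,0.7700
0.0005,0.8496
0.001,0.8673
0.0015,0.8661
0.006,0.7788
0.01,0.8407
0.02,0.5575
0.03,0.5310
0.04,0.5222
0.05,0.5841
0.06,0.5398
0.07,0.4779
0.08,0.5439
0.09,0.4602
0.1,0.4248
0.2,0.4602
0.3,0.4690
0.4,0.4779
0.5,0.3717
0.6,0.3513
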