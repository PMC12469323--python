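budget,equal_best,variable_best
5,61.34,88.49
10,70.42,88.49
20,76.65,88.49
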