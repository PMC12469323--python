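budget,equal_best,variable_best
5,59.22,86.88
10,66.24,86.88
20,71.61,86.88
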