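budget,equal_best,variable_best
5,78.23,98.13
10,82.45,98.13
20,85.60,98.13
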