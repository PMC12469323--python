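budget,equal_best,variable_best
5,62.12,96.33
10,76.37,96.33
20,77.60,96.33
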