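budget,equal_best,variable_best
5,83.10,96.54
10,85.34,96.54
20,85.34,96.54
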