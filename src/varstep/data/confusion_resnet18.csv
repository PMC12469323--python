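class,tp,fp,fn
perch,80,6,0
snapper,78,4,2
cod,73,3,7
other,67,9,13
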