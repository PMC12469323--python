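class,tp,fp,fn
perch,75,80,0
snapper,80,0,0
cod,78,5,2
other,75,0,5
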