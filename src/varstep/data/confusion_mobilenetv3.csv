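class,tp,fp,fn
perch,80,4,0
snapper,80,0,0
cod,80,4,0
other,72,0,8
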