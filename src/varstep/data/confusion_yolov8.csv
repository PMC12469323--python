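class,tp,fp,fn
perch,80,2,0
snapper,77,0,3
cod,79,17,1
other,64,1,16
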