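class,tp,fp,fn
perch,77,6,3
snapper,77,0,3
cod,76,5,4
other,69,10,11
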