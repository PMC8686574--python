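tissue	germ_layer
blood	mesoderm
saliva	mesoderm
buccal	ectoderm
hair	ectoderm
nail	ectoderm
urine	endoderm
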