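taxon	observation	source
F1	2-Methoxy-3-methyl-1,4-benzoquinone	literature
F1	toluquinone	gcms
F1	phenol	gcms
F2	1,4-Benzoquinone	literature
F2	benzoquinones-hydroquinones	literature
F3	phenol	literature
F4	phenol	gcms
F5	Hydroquinone	gcms
F6	terpenes	literature
F6	alpha-terpinene	gcms
F7	cyanogenics	literature
F7	benzoyl cyanide	gcms
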