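# Literature-reported anti-hyperuricemia compounds of Plantaginis Herba.
# Acteoside is also known as verbascoside.
mol_id	name	ob	dl	source
MOL003333	Acteoside	2.94	0.62	literature
MOL005734	Eupatilin	29.39	0.38	literature
MOL005305	Nepetin	26.75	0.31	literature
MOL009297	Jaceosidin	2.14	0.34	literature
MOL001733	Eupatorin	30.23	0.37	literature
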