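mol_id	name	ob	dl	source
MOL001735	Dinatin	30.97	0.27	database
MOL002714	Baicalein	33.52	0.21	database
MOL002776	Baicalin	40.12	0.75	database
MOL000359	Sitosterol	36.91	0.75	database
MOL004004	6-OH-Luteolin	46.93	0.28	database
MOL000449	Stigmasterol	43.83	0.76	database
MOL000006	Luteolin	36.16	0.25	database
MOL007783	Melampyroside	57.5	0.8	database
MOL007796	Stigmasterol palmitate	38.09	0.4	database
MOL007799	beta-Sitosterol palmitate	30.91	0.4	database
MOL003333	Acteoside	2.94	0.62	database
MOL005734	Eupatilin	29.39	0.38	database
MOL005305	Nepetin	26.75	0.31	database
MOL009297	Jaceosidin	2.14	0.34	database
MOL001733	Eupatorin	30.23	0.37	database
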