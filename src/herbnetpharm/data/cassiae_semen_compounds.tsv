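mol_id	name	ob	dl
MOL002268	Rhein	47.07	0.28
MOL002281	Toralactone	46.46	0.24
MOL000449	Stigmasterol	43.83	0.76
MOL000471	Aloe emodin	83.38	0.24
MOL005043	Campesterol	37.58	0.71
MOL006465	Rubrofusarin gentiobioside	40.12	0.67
MOL006466	Rubrofusarin	45.55	0.24
MOL006472	Aurantio-obtusin	31.55	0.37
MOL006475	Obtusin	81.43	0.4
MOL006481	Gluco-obtusifolin	42.41	0.81
MOL006482	9,10-Dihydroxy-7-methoxy-3-methylene-4H-benzo[g]isochromen-1-one	63.25	0.24
MOL006489	Quinizarin	47.34	0.19
MOL000953	CLR	37.87	0.68
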