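protein_accession	description	subcellular_localization	protein_size	succinylated_sites	dss	fold_change
Gene0008940.1	Succinate-semialdehyde dehydrogenase	mitochondria	530	K394/K442	K394	1.66
Gene0107960.1	ATPase_AAA_core domain-containing protein	chloroplast	443	K147/K167/K 171/K218/K221/K302/K359/K368	K167	0.57
Gene0157630.1	60S ribosomal protein L9	cytoplasm	194	K167	K167	0.66
Gene0282600.1	Glycolate oxidase	cytoplasm	367	K132/K135/K150	K150	0.61
Gene0315380.1	Glutathione S-transferase	chloroplast	217	K52/K197	K197	0.64
Gene0500950.1	Non-specific lipid-transfer protein	extracellular	118	K98/K107/K110	K98	2.01
Gene0163880.1	Catalase 3	peroxisome	492	K396/K481	K396	1.62
Gene0199220.1	2-oxoglutarate dehydrogenase, E1 subunit	mitochondria	1016	K352/K518/K602	K352	1.70
Gene0199220.1	2-oxoglutarate dehydrogenase, E1 subunit	mitochondria	1016	K352/K518/K602	K602	1.55
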