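sample_id	sex	phenotypes	cnv_type	chrom	start	end	size_kb	marker_count	region	cohort_freq	cnv_class	dgv_freq	clinical_freq	clinical_phenotypes	major_genes
SV039	M	SV;CAVC;PS	Del	14	60756434	61430513	674	94	14q23.1	0.3861 (1/259)	N-causative	0.0176			
SV130	F	SV;SA;CAVC	Dup	X	149504294	150375282	871	91	Xq28	0.3861 (1/259)	N-causative	0.8100			
SV136	M	SV;MGA;PS	Del	22	38016208	38115650	99	69	22q13.1	0.3861 (1/259)	N-causative	0.0046			
SV139	F	SV;CAVC;MGA;SA	Dup	2	215435747	216250781	815	73	2q35	0.3861 (1/259)	N-causative	N.A			
SV140	M	SV;ASD;MGA	Dup	2	109713114	110674457	961	111	2q13	0.3861 (1/259)	N-causative	0.0742			
SV143	M	SV;BRSI;CAVC;MGA;SA	Dup	2	120423759	121529013	1105	154	2q14.2	0.3861 (1/259)	N-causative	N.A			
SV168	F	SV;ASD;PDA;PA	Del	22	38031511	38115657	84	67	22q13.1	0.3861 (1/259)	N-causative	0.0046			
SV176	M	SV;VSD;SA;PS	Dup	7	30969138	31111965	143	79	7p14.3	0.3861 (1/259)	N-causative	0.0324			
SV220	M	SV;BRSI;MGA;SA	Del	5	70952592	71144199	192	101	5q13.2	0.3861 (1/259)	N-causative	1.5418			
SV226	F	SV;BRSI;MGA;SA;AVVR	Dup	5	127821735	128377797	556	89	5q23.2-5q23.3	0.3861 (1/259)	N-causative	N.A			
SV228	M	SV;DORV;CAVC;PFO	Dup	17	36101999	36481789	380	59	17q12	0.3861 (1/259)	N-causative	0.3247			
SV261	F	SV;CAVC;DEXTROCARDIA;PS;MGA;SA	Dup	X	10789416	11070136	281	131	Xp22.2	0.3861 (1/259)	N-causative	0.0046			
SV261	F	SV;CAVC;DEXTROCARDIA;PS;MGA;SA	Dup	7	40813257	41931182	1118	79	7p14.1	0.3861 (1/259)	P-causative		0.0104 (4/38367)	VSD	INHBA
SV143	M	SV;BRSI;CAVC;MGA;SA	Dup	5	167970535	169617000	1646	154	5q34-5q35.1	0.3861 (1/259)	P-causative		0.0391 (15/38367)	VSD;COA	TENM2,SLIT3
SV147	F	SV;ASD;SA	Dup	X	100407113	101349032	942	136	Xq22.1	0.3861 (1/259)	P-causative		0.1277 (49/38367)	VSD	PCDH19
SV163	M	SV;TGA;COA	Dup	1	225487757	227180965	1693	238	1q42.12-1q42.13	0.3861 (1/259)	P-causative		0.0547 (21/38367)	VSD	LEFTY1,LEFTY2
SV195	M	SV;MESOCARDIA;PS;SA;MGA;ASI	Dup	2	71674242	72187074	513	66	2p13.2	0.3861 (1/259)	P-causative		0.0078 (3/38367)	VSD	CYP26B1
SV007	M	SV;SA;PS	Del	8	80259789	88874526	8615	581	8q21.13-8q21.3	0.3861 (1/259)	P-causative		0.0860 (33/38367)	TOF;VSD	ZBTB10
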