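sample_id	sex	phenotypes	cnv_type	chrom	start	end	size_kb	marker_count	region	cohort_freq	cnv_class	dgv_freq	clinical_freq	clinical_phenotypes	major_genes
CAVC149	M	CAVC;DORV;TAPVC;SA	Dup	Y	16174790	18642949	2468	104	Yq11.221-11.222	0.3817 (1/262)	N-causative	0.0545			
CAVC084	M	CAVC;ASD;AVVR	Del	Y	6492863	9264427	2772	163	Yp11.2	0.3817 (1/262)	N-causative	0.0138			
CAVC142	M	CAVC;ASD;PFO	Del	17	42673287	42903979	231	122	17q21.2-17q21.31	0.3817 (1/262)	N-causative	N.A			
CAVC274	F	CAVC;PFO	Dup	3	99471505	100319058	848	70	3q12.1-3q12.2	0.3817 (1/262)	P-causative		0.0130 (5/38367)	VSD	TBC1D23
CAVC145	F	CAVC;PDA;PH	Del	8	141845636	144390430	2545	396	8q24.3	0.3817 (1/262)	P-causative		0.0417 (16/38367)	VSD;CAVC;ASD;TOF	PUF60
CAVC102	F	CAVC;PDA;PFO	Del	8	78588699	84286313	5698	373	8q21.13-8q21.2	0.3817 (1/262)	P-causative		0.0678 (26/38367)	TOF;VSD	STMN2,ZBTB10
CAVC162	M	CAVC;DORV	Del	7	73230400	74752194	1522	256	7q11.23	0.3817 (1/262)	P-causative		0.3360 (129/38367)	CAVC	ELN
CAVC207	F	CAVC;ASD;AVVR	Dup	9	18721	38816830	38798	4451	9p24.3-9p13.1	0.3817 (1/262)	P-causative		0.8106 (311/38367)	TOF;TGA;COA	uncertain
CAVC084	M	CAVC;ASD;AVVR	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3	14.8855 (39/262)	P-causative		0.5578 (214/38367)	ASD;VSD;TOF;HLHS	
CAVC142	M	CAVC;ASD;PFO	Dup	21	13038109	46443844	33406	3433	21q11.2-21q22.3		P-causative				
CAVC003	F	CAVC;TOF	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC006	M	CAVC;TOF;ASD	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC035	M	CAVC;ASD;PDA	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC050	M	CAVC;ASD;VSD	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC056	F	CAVC;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC061	F	CAVC;ASD;PDA	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC083	F	CAVC;PDA;AVVR	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC085	F	CAVC;PFO;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC088	F	CAVC;ASD;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC115	F	CAVC;ASD;AVVR	Dup	21	13038109	46687133	33649	3441	21q11.2-21q22.3		P-causative				
CAVC117	F	CAVC;ASD;PS	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC120	F	CAVC;PFO;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC137	F	CAVC;ASD;PDA	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC138	F	CAVC;PFO;AVVR	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC158	M	CAVC;PH;AVVR	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC164	M	CAVC;PFO;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC181	F	CAVC;ASD;PH	Dup	21	13038109	46687133	33649	3409	21q11.2-21q22.3		P-causative				
CAVC182	F	CAVC;ASD;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC215	F	CAVC;ASD;AVVR	Dup	21	13038109	43656492	30618	2869	21q11.2-21q22.3		P-causative				
CAVC225	M	CAVC;TOF;ASD	Dup	21	13038109	44280050	31242	2942	21q11.2-21q22.3		P-causative				
CAVC226	F	CAVC;ASD;AVVR	Dup	21	13038109	42995775	29958	2772	21q11.2-21q22.3		P-causative				
CAVC230	F	CAVC;PH;AVVR	Dup	21	13038109	43025182	29987	2774	21q11.2-21q22.3		P-causative				
CAVC232	M	CAVC;ASD;AVVR	Dup	21	13038109	42687189	29649	2753	21q11.2-21q22.3		P-causative				
CAVC237	F	CAVC;PH	Dup	21	13038109	43055843	30018	2784	21q11.2-21q22.3		P-causative				
CAVC241	M	CAVC;ASD;AVVR	Dup	21	13038109	44068398	31030	2955	21q11.2-21q22.3		P-causative				
CAVC248	F	CAVC;ASD;PH	Dup	21	13038109	46687133	33649	3425	21q11.2-21q22.3		P-causative				
CAVC250	F	CAVC;TOF;PDA	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC251	F	CAVC;ASD	Dup	21	13038109	46687133	33649	3434	21q11.2-21q22.3		P-causative				
CAVC252	M	CAVC;ASD;AVVR	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC253	M	CAVC;ASD;PH	Dup	21	13038109	44282471	31244	2976	21q11.2-21q22.3		P-causative				
CAVC259	M	CAVC;ASD;PH	Dup	21	13038109	45989774	32952	3232	21q11.2-21q22.3		P-causative				
CAVC260	F	CAVC;PDA;PS	Dup	21	13038109	43638875	30601	2902	21q11.2-21q22.3		P-causative				
CAVC264	F	CAVC;ASD;PH	Dup	21	13301510	44117172	30816	2948	21q11.2-21q22.3		P-causative				
CAVC268	M	CAVC;PDA;PFO	Dup	21	13038109	43789291	30751	2895	21q11.2-21q22.3		P-causative				
CAVC271	F	CAVC;ASD;PH	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
CAVC278	M	CAVC;PH	Dup	21	13038109	46440013	33402	3431	21q11.2-21q22.3		P-causative				
CAVC274	F	CAVC;PFO	Dup	21	13038109	46687133	33649	3449	21q11.2-21q22.3		P-causative				
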