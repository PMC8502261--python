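chr1	0	123400000	p36	gneg
chr1	123400000	225000000	q11	acen
chr1	225000000	226500000	q42.12	gneg
chr1	226500000	229000000	q42.13	gneg
chr1	229000000	248956422	q43	gneg
chr2	0	71000000	p25	gneg
chr2	71000000	73000000	p13.2	gneg
chr2	73000000	92000000	p13.1	gneg
chr2	92000000	108000000	q11	acen
chr2	108000000	112000000	q13	gneg
chr2	112000000	119000000	q14.1	gneg
chr2	119000000	123000000	q14.2	gneg
chr2	123000000	214000000	q21	gneg
chr2	214000000	218000000	q35	gneg
chr2	218000000	242193529	q36	gneg
chr3	0	91000000	p26	gneg
chr3	91000000	99000000	q11	acen
chr3	99000000	100000000	q12.1	gneg
chr3	100000000	101000000	q12.2	gneg
chr3	101000000	198295559	q13	gneg
chr5	0	48000000	p15	gneg
chr5	48000000	70000000	q11	acen
chr5	70000000	72000000	q13.2	gneg
chr5	72000000	127000000	q21	gneg
chr5	127000000	128200000	q23.2	gneg
chr5	128200000	130000000	q23.3	gneg
chr5	130000000	165000000	q31	gneg
chr5	165000000	169000000	q34	gneg
chr5	169000000	171000000	q35.1	gneg
chr5	171000000	181538259	q35.3	gneg
chr7	0	30000000	p22	gneg
chr7	30000000	32000000	p14.3	gneg
chr7	32000000	40000000	p14.2	gneg
chr7	40000000	42500000	p14.1	gneg
chr7	42500000	60000000	p11	acen
chr7	60000000	72000000	q11.21	gneg
chr7	72000000	76000000	q11.23	gneg
chr7	76000000	159345973	q21	gneg
chr8	0	45000000	p23	gneg
chr8	45000000	78000000	q11	acen
chr8	78000000	82000000	q21.13	gneg
chr8	82000000	86000000	q21.2	gneg
chr8	86000000	95000000	q21.3	gneg
chr8	95000000	140000000	q22	gneg
chr8	140000000	145138636	q24.3	gneg
chr9	0	2200000	p24.3	gneg
chr9	2200000	20000000	p22	gneg
chr9	20000000	38000000	p21	gneg
chr9	38000000	40500000	p13.1	gneg
chr9	40500000	70000000	q11	acen
chr9	70000000	138394717	q34	gneg
chr14	0	16000000	p11	acen
chr14	16000000	60000000	q12	gneg
chr14	60000000	62000000	q23.1	gneg
chr14	62000000	107043718	q24	gneg
chr17	0	25000000	p13	gneg
chr17	25000000	35800000	q11	acen
chr17	35800000	37000000	q12	gneg
chr17	37000000	42500000	q21.1	gneg
chr17	42500000	42800000	q21.2	gneg
chr17	42800000	45000000	q21.31	gneg
chr17	45000000	83257441	q22	gneg
chr21	0	5000000	p11	acen
chr21	5000000	13000000	q11.1	acen
chr21	13000000	15000000	q11.2	gneg
chr21	15000000	30000000	q21.1	gneg
chr21	30000000	42600000	q22.11	gneg
chr21	42600000	46709983	q22.3	gneg
chr22	0	15000000	p11	acen
chr22	15000000	37000000	q11	acen
chr22	37000000	40000000	q13.1	gneg
chr22	40000000	50818468	q13.2	gneg
chrX	0	9000000	p22.3	gneg
chrX	9000000	12000000	p22.2	gneg
chrX	12000000	60000000	p21	gneg
chrX	60000000	100000000	q21	gneg
chrX	100000000	102000000	q22.1	gneg
chrX	102000000	148000000	q23	gneg
chrX	148000000	156040895	q28	gneg
chrY	0	3000000	p11.32	gneg
chrY	3000000	10500000	p11.2	gneg
chrY	10500000	10700000	p11.1	acen
chrY	10700000	11000000	q11.1	acen
chrY	11000000	15000000	q11.21	gneg
chrY	15000000	17000000	q11.221	gneg
chrY	17000000	20000000	q11.222	gneg
chrY	20000000	26000000	q11.23	gneg
chrY	26000000	57227415	q12	gneg
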