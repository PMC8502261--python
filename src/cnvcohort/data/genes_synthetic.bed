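chr1	225900000	225905000	LEFTY1	0	-
chr1	226100000	226105000	LEFTY2	0	-
chr2	71900000	71920000	CYP26B1	0	-
chr2	71700000	71850000	EXOC6B	0	-
chr3	99500000	99680000	COL8A1	0	-
chr3	99700000	99830000	CMSS1	0	+
chr3	99750000	99920000	FILIP1L	0	+
chr3	100000000	100070000	TBC1D23	0	-
chr5	167990000	168900000	TENM2	0	+
chr5	168950000	169550000	SLIT3	0	-
chr7	40900000	40990000	SUGCT	0	+
chr7	41000000	41020000	INHBA	0	-
chr7	73240000	73250000	NCF1B	0	+
chr7	73328000	73360000	FKBP6	0	+
chr7	73400000	73442000	ELN	0	+
chr7	74650000	74760000	GTF2I	0	+
chr8	79600000	79650000	STMN2	0	+
chr8	80500000	80530000	ZBTB10	0	+
chr8	143800000	143815000	PUF60	0	-
chr9	3200000	3500000	RFX3	0	-
chr21	34360000	34460000	RCAN1	0	-
chr21	40010000	40850000	DSCAM	0	-
chr21	45981000	46005000	COL6A1	0	+
chr21	46098000	46132000	COL6A2	0	+
chrX	100900000	101000000	PCDH19	0	-
chrX	101050000	101090000	TNMD	0	+
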