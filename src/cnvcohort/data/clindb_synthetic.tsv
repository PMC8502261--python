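#kind=clinical
#coords=1-based
#n_total_records=38367
chrom	start	end	cnv_type	n_records	phenotypes
3	99471505	100319058	Dup	5	VSD
8	141845636	144390430	Del	16	VSD;CAVC;ASD;TOF
8	78588699	84286313	Del	26	TOF;VSD
7	73230400	74752194	Del	129	CAVC
9	18721	38816830	Dup	311	TOF;TGA;COA
21	13038109	46687133	Dup	214	ASD;VSD;TOF;HLHS
7	40813257	41931182	Dup	4	VSD
5	167970535	169617000	Dup	15	VSD;COA
X	100407113	101349032	Dup	49	VSD
1	225487757	227180965	Dup	21	VSD
2	71674242	72187074	Dup	3	VSD
8	82000000	88874526	Del	33	TOF;VSD
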