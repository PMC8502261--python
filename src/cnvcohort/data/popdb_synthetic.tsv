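#kind=population
#coords=1-based
chrom	start	end	cnv_type	frequency
Y	16174790	18642949	Dup	0.000545
Y	6492863	9264427	Del	0.000138
17	42673287	42903979	Del	0.005
14	60756434	61430513	Del	0.000176
X	149504294	150375282	Dup	0.0081
22	38016208	38115657	Del	4.6e-05
2	215435747	216250781	Dup	0.005
2	109713114	110674457	Dup	0.000742
2	120423759	121529013	Dup	0.005
7	30969138	31111965	Dup	0.000324
5	70952592	71144199	Del	0.015418
5	127821735	128377797	Dup	0.005
17	36101999	36481789	Dup	0.003247
X	10789416	11070136	Dup	4.6e-05
9	18721	19400000	Dup	0.001
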