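#name=GRCh38-subset
chrom	length	covered_start	covered_end
1	248956422	500000	248456422
2	242193529	500000	241693529
3	198295559	500000	197795559
5	181538259	500000	181038259
7	159345973	500000	158845973
8	145138636	500000	144638636
9	138394717	500000	137894717
14	107043718	16000000	106543718
17	83257441	500000	82757441
21	46709983	13000000	46700000
22	50818468	15000000	50318468
X	156040895	500000	155540895
Y	57227415	2700000	26600000
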