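ELN
PUF60
ZBTB10
STMN2
TBC1D23
LEFTY1
LEFTY2
SLIT3
TENM2
PCDH19
CYP26B1
INHBA
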