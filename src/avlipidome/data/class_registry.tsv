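subclass	category	headgroup_formula	n_chain_slots	linkage
CE	NL	C27H46O	1	ester
TG	NL	C3H8O3	3	ester
DG	NL	C3H8O3	2	ester
MG	NL	C3H8O3	1	ester
FA	NL	-	1	free
ST	ST	C27H46O	0	lookup
PC	GPL	C8H20NO6P	2	ester
PE	GPL	C5H14NO6P	2	ester
etherPE	GPL	C5H14NO6P	2	ester
PS	GPL	C6H14NO8P	2	ester
PI	GPL	C9H19O11P	2	ester
PG	GPL	C6H15O8P	2	ester
PA	GPL	C3H9O6P	2	ester
CL	GPL	C9H22O13P2	4	ester
LPC	lysoGPL	C8H20NO6P	1	ester
LPE	lysoGPL	C5H14NO6P	1	ester
LPA	lysoGPL	C3H9O6P	1	ester
LPI	lysoGPL	C9H19O11P	1	ester
LPS	lysoGPL	C6H14NO8P	1	ester
SM	SP	C5H12NO3P	2	sphingo
Cer	SP	-	2	sphingo
dhCer	SP	-	2	sphingo
deoxyCer	SP	-	2	sphingo
phytoCer	SP	-	2	sphingo
sphingadienine-Cer	SP	-	2	sphingo
HexCer	SP	C6H10O5	2	sphingo
Hex2Cer	SP	C12H20O10	2	sphingo
GM3	SP	C23H37NO18	2	sphingo
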