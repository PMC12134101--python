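subclass	backbone_id	smiles
CE	sterol_ester	O=COC1CCC2(C)C(C1)CC=C1C2CCC2(C)C1CCC2
ST	sterol	OC1CCC2(C)C(C1)CC=C1C2CCC2(C)C1CCC2
TG	glycerol	OCC(O)CO
DG	glycerol	OCC(O)CO
MG	glycerol	OCC(O)CO
FA	fatty_acid	CC(=O)O
PC	gpc	C[N+](C)(C)CCOP([O-])(=O)OCC(O)CO
LPC	gpc	C[N+](C)(C)CCOP([O-])(=O)OCC(O)CO
PE	gpe	NCCOP(O)(=O)OCC(O)CO
LPE	gpe	NCCOP(O)(=O)OCC(O)CO
etherPE	gpe_plasmenyl	NCCOP(O)(=O)OCC(OC=C)CO
PS	gps	OC(=O)C(N)COP(O)(=O)OCC(O)CO
LPS	gps	OC(=O)C(N)COP(O)(=O)OCC(O)CO
PI	gpi	OC1C(O)C(O)C(O)C(O)C1OP(O)(=O)OCC(O)CO
LPI	gpi	OC1C(O)C(O)C(O)C(O)C1OP(O)(=O)OCC(O)CO
PG	gpg	OCC(O)COP(O)(=O)OCC(O)CO
PA	gpa	OP(O)(=O)OCC(O)CO
LPA	gpa	OP(O)(=O)OCC(O)CO
CL	cardiolipin	OCC(O)COP(O)(=O)OCC(O)COP(O)(=O)OCC(O)CO
Cer	sphingosine	CC=CC(O)C(N)CO
dhCer	sphinganine	CCCC(O)C(N)CO
deoxyCer	deoxysphingosine	CC=CC(O)C(N)C
phytoCer	phytosphingosine	CCC(O)C(O)C(N)CO
sphingadienine-Cer	sphingadienine	C=CC=CC(O)C(N)CO
SM	sphingomyelin	C[N+](C)(C)CCOP([O-])(=O)OCC(N)C(O)C=CC
HexCer	hexosylceramide	OCC1OC(OCC(N)C(O)C=CC)C(O)C(O)C1O
Hex2Cer	dihexosylceramide	OCC1OC(OCC2OC(OCC(N)C(O)C=CC)C(O)C(O)C2O)C(O)C(O)C1O
GM3	gm3_glycan	OC(=O)C1OC(OC2C(O)C(O)C(CO)OC2OCC(N)C(O)C=CC)C(O)C(N)C1O
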