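backbone_id	cardiolipin	deoxysphingosine	dihexosylceramide	fatty_acid	glycerol	gm3_glycan	gpa	gpc	gpe	gpe_plasmenyl	gpg	gpi	gps	hexosylceramide	phytosphingosine	sphingadienine	sphinganine	sphingomyelin	sphingosine	sterol	sterol_ester
cardiolipin	0.0	22.0	25.0	22.0	18.0	26.0	14.0	16.0	13.0	15.0	9.0	6.0	12.0	17.0	18.0	22.0	19.0	19.0	21.0	32.0	34.0
deoxysphingosine	22.0	0.0	25.0	6.0	6.0	26.0	10.0	14.0	11.0	13.0	13.0	18.0	12.0	13.0	4.0	2.0	3.0	11.0	1.0	20.0	22.0
dihexosylceramide	25.0	25.0	0.0	31.0	27.0	5.0	31.0	31.0	28.0	28.0	26.0	21.0	27.0	12.0	25.0	25.0	26.0	30.0	24.0	23.0	25.0
fatty_acid	22.0	6.0	31.0	0.0	4.0	30.0	8.0	14.0	11.0	13.0	13.0	20.0	12.0	19.0	8.0	8.0	7.0	17.0	7.0	22.0	24.0
glycerol	18.0	6.0	27.0	4.0	0.0	28.0	4.0	10.0	7.0	9.0	9.0	16.0	10.0	15.0	6.0	6.0	5.0	15.0	5.0	22.0	24.0
gm3_glycan	26.0	26.0	5.0	30.0	28.0	0.0	32.0	32.0	29.0	29.0	27.0	22.0	28.0	13.0	26.0	26.0	27.0	29.0	25.0	24.0	26.0
gpa	14.0	10.0	31.0	8.0	4.0	32.0	0.0	6.0	3.0	5.0	5.0	12.0	6.0	19.0	10.0	10.0	9.0	11.0	9.0	26.0	28.0
gpc	16.0	14.0	31.0	14.0	10.0	32.0	6.0	0.0	3.0	5.0	7.0	14.0	6.0	19.0	10.0	14.0	11.0	5.0	13.0	30.0	32.0
gpe	13.0	11.0	28.0	11.0	7.0	29.0	3.0	3.0	0.0	2.0	4.0	11.0	3.0	16.0	7.0	11.0	8.0	8.0	10.0	27.0	29.0
gpe_plasmenyl	15.0	13.0	28.0	13.0	9.0	29.0	5.0	5.0	2.0	0.0	6.0	13.0	5.0	16.0	9.0	11.0	10.0	8.0	12.0	27.0	29.0
gpg	9.0	13.0	26.0	13.0	9.0	27.0	5.0	7.0	4.0	6.0	0.0	7.0	3.0	14.0	9.0	13.0	10.0	12.0	12.0	27.0	29.0
gpi	6.0	18.0	21.0	20.0	16.0	22.0	12.0	14.0	11.0	13.0	7.0	0.0	10.0	13.0	14.0	18.0	15.0	15.0	17.0	26.0	28.0
gps	12.0	12.0	27.0	12.0	10.0	28.0	6.0	6.0	3.0	5.0	3.0	10.0	0.0	15.0	8.0	12.0	9.0	11.0	11.0	28.0	30.0
hexosylceramide	17.0	13.0	12.0	19.0	15.0	13.0	19.0	19.0	16.0	16.0	14.0	13.0	15.0	0.0	13.0	13.0	14.0	18.0	12.0	21.0	23.0
phytosphingosine	18.0	4.0	25.0	8.0	6.0	26.0	10.0	10.0	7.0	9.0	9.0	14.0	8.0	13.0	0.0	4.0	1.0	13.0	3.0	20.0	22.0
sphingadienine	22.0	2.0	25.0	8.0	6.0	26.0	10.0	14.0	11.0	11.0	13.0	18.0	12.0	13.0	4.0	0.0	3.0	11.0	1.0	20.0	22.0
sphinganine	19.0	3.0	26.0	7.0	5.0	27.0	9.0	11.0	8.0	10.0	10.0	15.0	9.0	14.0	1.0	3.0	0.0	12.0	2.0	19.0	21.0
sphingomyelin	19.0	11.0	30.0	17.0	15.0	29.0	11.0	5.0	8.0	8.0	12.0	15.0	11.0	18.0	13.0	11.0	12.0	0.0	10.0	27.0	29.0
sphingosine	21.0	1.0	24.0	7.0	5.0	25.0	9.0	13.0	10.0	12.0	12.0	17.0	11.0	12.0	3.0	1.0	2.0	10.0	0.0	21.0	23.0
sterol	32.0	20.0	23.0	22.0	22.0	24.0	26.0	30.0	27.0	27.0	27.0	26.0	28.0	21.0	20.0	20.0	19.0	27.0	21.0	0.0	2.0
sterol_ester	34.0	22.0	25.0	24.0	24.0	26.0	28.0	32.0	29.0	29.0	29.0	28.0	30.0	23.0	22.0	22.0	21.0	29.0	23.0	2.0	0.0
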