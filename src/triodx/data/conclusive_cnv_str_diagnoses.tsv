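patient	sex	concordance	gene	genomic_mutation	size	inheritance
33	female	GS+	CHD2	15q26.1(93494184-93499518)x1	5 kb	de novo
47	female	GS+	AHDC1	1p36.11(27833526-27869757)x1	36 kb	de novo
8	female	yes	CSNK2A1	20p13(486287-1783151)x1	1.3 Mb	de novo
8	female	yes	PDYN	20p13(1963481-1995077)x3	32 kb	de novo
25	male	yes	FMR1	X:146993568_146993628CGG[94]	94 repeat units	anticipation
117	male	yes	Multiple	16p11.2(29591089-30199431)3x	0.6 Mb	paternal
142	male	yes	Multiple	16p13.2(8165983-9074579)1x	0.9 Mb	de novo
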