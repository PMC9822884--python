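patient	sex	concordance	gene	genomic_mutation	cdna	protein	inheritance
2	female	yes	PACS1	Chr11(GRCh37):g.65978677C>T	NM_018026.3:c.607C>T	p.(Arg203Trp)	de novo
12	male	yes	SPEN	Chr1(GRCh37):g.16257748_16257752del	NM_015001.2:c.5013_5017del	p.(Glu1671Aspfs*16)	de novo
30	male	yes	TBR1	Chr2(GRCh37):g.162273598T>A	NM_006593.3:c.677T>A	p.(Ile226Asn)	de novo
35	male	yes	CDK13	Chr7(GRCh37):g.39990724dup	NM_003718.4:c.484dup	p.(Ala162Glyfs*108)	de novo
35	male	yes	TET3	Chr2(GRCh37):g.74326613C>T	NM_001287491.2:c.3478C>T	p.(Arg1160Cys)	de novo
39	female	yes	ANKRD11	Chr16(GRCh37):g.89346232C>A	NM_001256182.1:c.6718G>T	p.(Glu2240*)	de novo
40	female	yes	GATAD2B	Chr1(GRCh37):g.153791300_153791301del	NM_020699.2:c.565_566del	p.(Gln190Alafs*34)	de novo
49	male	yes	DOCK3	Chr3(GRCh37):g.51127708_51127711dup	NM_004947.4:c.639_642dup	p.(Pro214Ilefs*7)	homozygous
55	male	yes	ANKRD11	Chr16(GRCh37):g.89347820dup	NM_001256182.1:c.5130dup	p.(Ser1711Ilefs*21)	de novo
57	male	yes	SLC16A2	ChrX(GRCh37):g.73641601del	NM_006517.3:c.351del	p.(Val118Cysfs*40)	de novo
63	female	yes	MECP2	ChrX(GRCh37):g.153296476del	NM_001110792.1:c.842del	p.(Gly281Alafs*20)	de novo
66	female	yes	SHANK3	Chr22(GRCh37):g.51159604C>T	NM_001080420.1:c.3391C>T	p.(Arg1131*)	de novo
67	male	yes	CHD3	Chr17(GRCh37):g.7803968G>A	NM_001005271.2:c.3074G>A	p.(Arg1025Gln)	de novo
71	male	yes	TRIP12	Chr2(GRCh37):g.230632449G>T	NM_001348328.1:c.6028C>A	p.(Pro2010Thr)	de novo
73	male	yes	ATRX	ChrX(GRCh37):g.76875938T>C	NM_000489.3:c.5197A>G	p.(Lys1733Glu)	hemizygous
74	male	yes	ACTB	Chr7(GRCh37):g.5568193G>A	NM_001101.4:c.521C>T	p.(Ala174Val)	de novo
79	male	yes	BMP4	Chr14(GRCh37):g.54418925G>A	NM_001202.3:c.16C>T	p.(?)	de novo
80	male	yes	ANKRD11	Chr16(GRCh37):g.89351038_89351039del	NM_001256182.1:c.1914_1915del	p.(His638Glnfs*24)	de novo
82	male	yes	SHANK3	Chr22(GRCh37):g.51159940dup	NM_001080420.1:c.3727dup	p.(Ala1243Glyfs*69)	de novo
84	female	yes	MYCN	Chr2(GRCh37):g.16082228C>A	NM_001293228.1:c.42C>A	p.(Cys14*)	de novo
86	male	yes	WASF1	Chr6(GRCh37):g.110422797G>A	NM_003931.2:c.1516C>T	p.(Arg506*)	de novo
88	male	yes	CUL3	Chr2(GRCh37):g.225371574C>G	NC_000002.12(NM_001257198.1):c.1047+1G>C	p.(?)	de novo
96	female	yes	DDX3X	ChrX(GRCh37):g.41205496dup	NM_001356.4:c.1330dup	p.(Thr444Asnfs*21)	de novo
97	male	yes	SLC2A1	Chr1(GRCh37):g.43395707C>A	NC_000001.11(NM_006516.2):c.517-1G>T	p.(?)	de novo
98	male	yes	ABCD1	ChrX(GRCh37):g.153002655C>A	NM_000033.3:c.1438C>A	p.(Pro480Thr)	hemizygous
102	female	yes	DDX3X	ChrX(GRCh37):g.41203054C>T	NM_001356.4:c.744C>T	p.(Gly248=)	de novo
107	male	yes	KDM5C	ChrX(GRCh37):g.53223539C>T	NM_004187.3:c.3820G>A	p.(Glu1274Lys)	de novo
109	male	yes	PPM1D	Chr17(GRCh37):g.58734161dup	NM_003620.3:c.1219dup	p.(Cys407Leufs*27)	de novo
110	female	yes	FOXP2	Chr7(GRCh37):g.114292307C>T	NM_148898.3:c.1219C>T	p.(Arg407*)	de novo
113	male	yes	KCNQ2	Chr20(GRCh37):g.62076675G>A	NM_172107.2:c.430C>T	p.(Arg144Trp)	de novo
116	female	yes	FBXO11	Chr2(GRCh37):g.48132751G>A	NM_001190274.1:c.109C>T	p.(Gln37*)	de novo
120	male	yes	ANKRD11	Chr16(GRCh37):g.89349832T>A	NM_001256182.1:c.3118A>T	p.(Lys1040*)	de novo
121	female	yes	DEAF1	Chr11(GRCh37):g.686982C>T	NM_021008.3:c.680G>A	p.(Cys227Tyr)	de novo
124	male	yes	KAT6A	Chr8(GRCh37):g.41791983del	NM_006766.4:c.3756del	p.(Ser1253Leufs*41)	de novo
132	female	yes	DDX3X	ChrX(GRCh37):g.41206602C>T	NM_001356.4:c.1807C>T	p.(Arg603*)	de novo
133	male	yes	GRIA3	ChrX(GRCh37):g.122561802G>A	NM_000828.4:c.1888G>A	p.(Gly630Arg)	hemizygous
139	female	yes	GNB1	Chr1(GRCh37):g.1735941C>T	NM_002074.4:c.347G>A	p.(Gly116Asp)	de novo
140	male	yes	NFIX	Chr19(GRCh37):g.13184270del	NM_001271043.2:c.681del	p.(Val229Serfs*4)	de novo
144	male	yes	FOXG1	Chr14(GRCh37):g.29237130C>A	NM_005249.4:c.645C>A	p.(Phe215Leu)	de novo
146	male	yes	KCNQ2	Chr20(GRCh37):g.62044909G>A	NM_172107.2:c.1657C>T	p.(Arg553Trp)	de novo
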