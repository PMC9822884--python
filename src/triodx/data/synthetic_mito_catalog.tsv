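position	ref	alt	phenotype
1555	A	G	Aminoglycoside-induced and nonsyndromic deafness
3243	A	G	MELAS / maternally inherited diabetes-deafness
3460	G	A	LHON
8344	A	G	MERRF
8993	T	G	NARP / Leigh syndrome
8993	T	C	NARP / Leigh syndrome
11778	G	A	LHON
14484	T	C	LHON
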