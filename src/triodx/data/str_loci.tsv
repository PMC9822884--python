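gene	chrom	start	end	motif	premutation_threshold	pathogenic_threshold
AFF2	X	147582159	147582212	GCC	.	200
ARX	X	25031766	25031813	GCN	.	20
CSTB	21	45196324	45196359	CCCCGCCCCGCG	.	30
EIF4A3	17	78103111	78103170	CCTCGCTGTGCCGCTGCCGA	.	14
DMPK	19	46273463	46273525	CTG	.	50
FMR1	X	146993568	146993627	CGG	55	200
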