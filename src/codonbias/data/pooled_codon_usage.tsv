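# Pooled codon usage over the protein-coding genes of 32 published
# mycobacteriophage genomes: codon count (n) and RSCU as printed in the
# published survey. Stop-codon RSCU printed as 0.00 by convention.
aa	codon	n	rscu_printed
Phe	UUU	1795	0.20
Phe	UUC	15765	1.80
Leu	UUA	195	0.03
Leu	UUG	5037	0.66
Ser	UCU	2127	0.40
Ser	UCC	7032	1.32
Ser	UCA	1889	0.35
Ser	UCG	10888	2.04
Tyr	UAU	2447	0.31
Tyr	UAC	13288	1.69
Ter	UAA	393	0.00
Ter	UAG	388	0.00
Cys	UGU	874	0.33
Cys	UGC	4496	1.67
Ter	UGA	1365	0.00
Trp	UGG	11727	1.00
Leu	CUU	2805	0.37
Leu	CUC	13867	1.82
Leu	CUA	1400	0.18
Leu	CUG	22302	2.93
Pro	CCU	3503	0.42
Pro	CCC	10146	1.21
Pro	CCA	2630	0.31
Pro	CCG	17369	2.06
His	CAU	2427	0.40
His	CAC	9611	1.60
Gln	CAA	3076	0.30
Gln	CAG	17766	1.70
Arg	CGU	5190	0.83
Arg	CGC	16237	2.60
Arg	CGA	3195	0.51
Arg	CGG	9987	1.60
Ile	AUU	3524	0.40
Ile	AUC	21992	2.52
Ile	AUA	636	0.07
Met	AUG	11923	1.00
Thr	ACU	2990	0.32
Thr	ACC	20215	2.20
Thr	ACA	2910	0.32
Thr	ACG	10698	1.16
Asn	AAU	2886	0.29
Asn	AAC	16738	1.71
Lys	AAA	3185	0.29
Lys	AAG	18997	1.71
Ser	AGU	1693	0.32
Ser	AGC	8424	1.58
Arg	AGA	692	0.11
Arg	AGG	2110	0.34
Val	GUU	4218	0.40
Val	GUC	18361	1.73
Val	GUA	1855	0.17
Val	GUG	17981	1.70
Ala	GCU	7738	0.50
Ala	GCC	26730	1.72
Ala	GCA	6591	0.42
Ala	GCG	21142	1.36
Asp	GAU	8082	0.42
Asp	GAC	30303	1.58
Glu	GAA	8983	0.50
Glu	GAG	26657	1.50
Gly	GGU	10057	0.78
Gly	GGC	27920	2.17
Gly	GGA	5241	0.41
Gly	GGG	8345	0.65
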