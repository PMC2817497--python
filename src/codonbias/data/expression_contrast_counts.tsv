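# Pooled codon counts and printed RSCU for the 10% extreme-left (putatively
# highly expressed, 'left') and extreme-right ('right') gene groups on CA
# axis 1 of the 32-mycobacteriophage survey. The printed left-group RSCU
# for AAU (1.10) is a typo inconsistent with its two-fold family sum;
# the value stored here (0.10) is recomputed from the printed counts.
aa	codon	n_left	rscu_left_printed	n_right	rscu_right_printed
Phe	UUU	34	0.08	185	0.57
Phe	UUC	839	1.92	466	1.43
Leu	UUA	0	0.00	41	0.16
Leu	UUG	33	0.09	390	1.55
Ser	UCU	27	0.11	178	0.94
Ser	UCC	284	1.20	166	0.88
Ser	UCA	23	0.10	160	0.84
Ser	UCG	417	1.76	317	1.67
Tyr	UAU	41	0.10	185	0.69
Tyr	UAC	767	1.90	350	1.31
Ter	UAA	20	0.56	28	0.79
Ter	UAG	24	0.67	21	0.59
Cys	UGU	7	0.06	123	0.83
Cys	UGC	212	1.94	175	1.17
Ter	UGA	63	1.77	58	1.63
Trp	UGG	531	1.00	468	1.00
Leu	CUU	26	0.07	235	0.93
Leu	CUC	518	1.38	292	1.16
Leu	CUA	5	0.01	123	0.49
Leu	CUG	1676	4.45	429	1.70
Pro	CCU	60	0.16	249	0.85
Pro	CCC	545	1.49	257	0.88
Pro	CCA	43	0.12	209	0.71
Pro	CCG	813	2.23	459	1.56
His	CAU	36	0.12	236	0.89
His	CAC	570	1.88	296	1.11
Gln	CAA	29	0.06	221	0.63
Gln	CAG	1021	1.94	480	1.37
Arg	CGU	164	0.52	364	1.37
Arg	CGC	1189	3.79	399	1.50
Arg	CGA	55	0.18	227	0.85
Arg	CGG	442	1.41	328	1.23
Ile	AUU	78	0.19	288	1.01
Ile	AUC	1181	2.81	495	1.74
Ile	AUA	1	0.00	72	0.25
Met	AUG	648	1.00	427	1.00
Thr	ACU	47	0.09	217	0.78
Thr	ACC	1573	3.11	333	1.20
Thr	ACA	33	0.07	193	0.70
Thr	ACG	367	0.73	364	1.32
Asn	AAU	50	0.10	265	0.75
Asn	AAC	926	1.90	446	1.25
Lys	AAA	33	0.06	229	0.60
Lys	AAG	1046	1.94	539	1.40
Ser	AGU	27	0.11	139	0.73
Ser	AGC	642	2.71	178	0.94
Arg	AGA	1	0.00	109	0.41
Arg	AGG	33	0.11	170	0.64
Val	GUU	88	0.15	332	0.92
Val	GUC	1131	1.97	373	1.04
Val	GUA	48	0.08	123	0.34
Val	GUG	1025	1.79	608	1.69
Ala	GCU	183	0.22	428	0.91
Ala	GCC	2078	2.50	483	1.03
Ala	GCA	181	0.22	355	0.76
Ala	GCG	882	1.06	611	1.30
Asp	GAU	151	0.15	564	0.89
Asp	GAC	1868	1.85	706	1.11
Glu	GAA	270	0.29	513	0.84
Glu	GAG	1609	1.71	704	1.16
Gly	GGU	305	0.54	414	1.04
Gly	GGC	1646	2.90	471	1.19
Gly	GGA	81	0.14	363	0.91
Gly	GGG	235	0.41	341	0.86
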