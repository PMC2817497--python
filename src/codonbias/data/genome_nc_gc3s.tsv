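# Per-genome mean (sd) effective number of codons and GC3s (%) for the
# 32 published mycobacteriophage genomes.
genome	nc_mean	nc_sd	gc3s_mean	gc3s_sd
244	38.98	6.96	80.65	7.87
Bxb1	40.17	7.28	80.05	7.334
Bxz2	37.93	5.7	82.72	6.46
Che9c	39.48	6.96	81.01	7.842
Rosebush	32.53	4.04	88.44	4.27
Omega	43.91	6.54	75.49	7.01
Halo	37.87	5.24	82.46	5.59
Barnyard	47.96	7.24	65.84	8.87
Bxz1	35.8	5.64	85.09	6.48
Cjw1	38.8	6.4	80.64	7.83
Corndog	37.87	6.69	82.65	7.23
Orion	37.79	5.55	82.85	5.17
Plot	44.28	5.69	73.35	6.59
Llij	43.52	6.18	72.23	5.51
Pipefish	35.12	3.55	87.35	3.53
PMC	42.62	6.28	71.95	5.3
Qyrzula	32.45	3.93	88.56	4.37
Wildcat	47.62	6.63	66.37	6.29
D29	37.83	5.28	82.58	5.59
L5	40.67	5.7	80.79	5.86
PBI1	44.07	5.67	73.71	6.63
PG1	37.59	5.2	82.7	4.9
Cooper	31.44	4.65	89.35	5.9
Che12	39.06	4.83	81.94	5.75
Catera	35.44	5.66	85.53	6.24
TM4	34.07	3.6	88.19	4.64
Che8	43.62	6.33	70.57	5.37
Tweety	42.76	5.81	72.07	5.51
U2	39.58	7.03	81.1	7.26
Bethlehem	40.22	6.98	80.35	6.57
Giles	36.48	5.04	83.38	5.24
Che9d	44.1	7.13	71.6	5.8
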