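# Pooled codon counts of the 431 highest- and 431 lowest-scoring genes on the
# expression axis (top/bottom 5% of 8,620 T. multiceps CDSs), with published RSCU
# values and the published optimal-codon flag (asterisks in the source table)
aa	codon	high_count	high_rscu_published	low_count	low_rscu_published	optimal_published
Ala	GCU	2436	1.09	3404	1.27	0
Ala	GCC	3133	1.40	2575	0.96	1
Ala	GCA	1686	0.75	2780	1.04	0
Ala	GCG	1691	0.76	1955	0.73	0
Arg	CGU	1377	1.52	2285	1.28	1
Arg	CGC	1460	1.61	1841	1.03	1
Arg	CGA	1040	1.15	1972	1.10	0
Arg	CGG	707	0.78	1286	0.72	0
Arg	AGA	421	0.46	1808	1.01	0
Arg	AGG	429	0.47	1523	0.85	0
Asn	AAU	1721	0.87	3282	1.21	0
Asn	AAC	2251	1.13	2132	0.79	1
Asp	GAU	1832	0.91	4650	1.20	0
Asp	GAC	2215	1.09	3082	0.80	1
Cys	UGU	1565	0.87	806	1.11	0
Cys	UGC	2036	1.13	649	0.89	1
Gln	CAA	1319	0.86	3748	1.01	0
Gln	CAG	1755	1.14	3698	0.99	1
Glu	GAA	1403	0.70	8782	1.01	0
Glu	GAG	2606	1.30	8660	0.99	1
Gly	GGU	2761	1.34	1483	1.37	0
Gly	GGC	2917	1.41	997	0.92	1
Gly	GGA	1665	0.81	1110	1.03	0
Gly	GGG	919	0.44	739	0.68	0
His	CAU	1079	0.80	1275	1.10	0
His	CAC	1630	1.20	1052	0.90	1
Ile	AUU	2541	1.06	2609	1.42	0
Ile	AUC	3644	1.52	1605	0.87	1
Ile	AUA	1019	0.42	1292	0.70	0
Leu	UUA	555	0.25	1404	0.63	0
Leu	UUG	1723	0.79	3125	1.41	0
Leu	CUU	2413	1.10	2910	1.32	0
Leu	CUC	4437	2.03	1864	0.84	1
Leu	CUA	1096	0.50	1375	0.62	0
Leu	CUG	2917	1.33	2592	1.17	1
Lys	AAA	1230	0.79	5661	0.95	0
Lys	AAG	1865	1.21	6277	1.05	1
Met	AUG	2622	1.00	2746	1.00	0
Phe	UUU	2687	0.78	1612	1.13	0
Phe	UUC	4172	1.22	1229	0.87	1
Pro	CCU	1557	1.05	985	1.15	0
Pro	CCC	2037	1.37	703	0.82	1
Pro	CCA	1336	0.90	1163	1.36	0
Pro	CCG	1026	0.69	575	0.67	0
Ser	UCU	1455	1.01	1901	1.14	0
Ser	UCC	2224	1.54	1678	1.01	1
Ser	UCA	1079	0.75	1937	1.16	0
Ser	UCG	1294	0.90	1389	0.83	0
Ser	AGU	1231	0.85	1785	1.07	0
Ser	AGC	1372	0.95	1295	0.78	0
Thr	ACU	1663	1.02	1879	1.16	0
Thr	ACC	2449	1.50	1492	0.92	1
Thr	ACA	1262	0.77	1756	1.08	0
Thr	ACG	1153	0.71	1380	0.85	0
Trp	UGG	1904	1.00	714	1.00	0
Tyr	UAU	1234	0.59	1239	1.05	0
Tyr	UAC	2920	1.41	1124	0.95	1
Val	GUU	2027	0.90	2157	1.37	0
Val	GUC	2837	1.26	1249	0.79	1
Val	GUA	948	0.42	989	0.63	0
Val	GUG	3213	1.42	1890	1.20	1
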