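# Genome-wide codon usage of the T. multiceps adult transcriptome (8,620 CDSs)
# rscu_published: RSCU value as printed in the source publication
aa	codon	count	rscu_published
Ala	GCU	66571	1.26
Ala	GCC	60219	1.14
Ala	GCA	46898	0.89
Ala	GCG	37647	0.71
Arg	CGU	41703	1.44
Arg	CGC	36670	1.27
Arg	CGA	34400	1.19
Arg	CGG	21406	0.74
Arg	AGA	20593	0.71
Arg	AGG	18942	0.65
Asn	AAU	61374	1.07
Asn	AAC	53482	0.93
Asp	GAU	83678	1.10
Asp	GAC	67932	0.90
Cys	UGU	28391	0.99
Cys	UGC	29110	1.01
Gln	CAA	51821	0.95
Gln	CAG	57603	1.05
Glu	GAA	86515	0.92
Glu	GAG	101456	1.08
Gly	GGU	56752	1.41
Gly	GGC	45893	1.14
Gly	GGA	37411	0.93
Gly	GGG	21005	0.52
His	CAU	31625	0.95
His	CAC	34908	1.05
Ile	AUU	65463	1.32
Ile	AUC	56412	1.14
Ile	AUA	26796	0.54
Leu	UUA	20522	0.43
Leu	UUG	54091	1.13
Leu	CUU	62280	1.30
Leu	CUC	66010	1.37
Leu	CUA	28125	0.59
Leu	CUG	57257	1.19
Lys	AAA	66198	0.90
Lys	AAG	80146	1.10
Phe	UUU	56781	0.97
Phe	UUC	56843	1.03
Pro	CCU	38993	1.11
Pro	CCC	38260	1.09
Pro	CCA	37916	1.08
Pro	CCG	25730	0.73
Ser	UCU	41504	1.13
Ser	UCC	43482	1.18
Ser	UCA	36776	1.00
Ser	UCG	33005	0.89
Ser	AGU	35197	0.95
Ser	AGC	31355	0.85
Thr	ACU	44571	1.17
Thr	ACC	43688	1.14
Thr	ACA	36206	0.95
Thr	ACG	28553	0.75
Tyr	UAU	33694	0.82
Tyr	UAC	48161	1.18
Val	GUU	55062	1.19
Val	GUC	47059	1.02
Val	GUA	23416	0.51
Val	GUG	59224	1.28
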