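group	scope	alc	fwd_id	fwd_seq	f_first	f_last	rev_id	rev_seq	r_first	r_last	span_printed	region
panel	bacteria	S	KP_F048	TACGGRAGGCAGCAG	342	356	OP_R043	CCGCGRCTGCTGGCAC	514	529	187	V3-V4
panel	bacteria	S	OP_F098	CCAGCAGCYGCGGTAAN	517	533	OP_R119	GGACTACCRGGGTATCTAA	787	805	288	V4-V5
panel	bacteria	S	OP_F066	GGMTTAGATACCC	784	796	KP_R040	CCGTCAATTCMTTTGAGTTT	906	925	141	V5-V6
panel	bacteria	S	OP_F009	GGATTAGATACCCBRGTAGTC	784	804	OP_R030	TCACRRCACGAGCTGWCGAC	1060	1079	295	V5-V7
panel	bacteria	S	KP_F061	ACTCAAAKGAATWGACGG	908	925	KP_R074	GGGTYKCGCTCGTTR	1099	1113	205	V6-V7
panel	bacteria	S	OP_F101	GAATTGRCGGGGRCC	916	930	OP_R030	TCACRRCACGAGCTGWCGAC	1060	1079	163	V6-V7
panel	bacteria	M	OP_F053	GRGTTYGATYMTGGCTCAG	9	27	KP_R020	CTGCTGCCTYCCGTA	342	356	347	V1-V3
panel	bacteria	M	KP_F048	TACGGRAGGCAGCAG	342	356	KP_R031	TACHVGGGTATCTAAKCC	784	801	459	V3-V5
panel	bacteria	M	KP_F048	TACGGRAGGCAGCAG	342	356	OP_R073	CRTACTHCHCAGGYG	879	893	551	V3-V6
panel	bacteria	M	KP_F051	GTGCCAGCMGCNGCGG	514	529	KP_R041	CGTCAATTCMTTTGAGTT	907	924	410	V4-V6
panel	bacteria	M	KP_F051	GTGCCAGCMGCNGCGG	514	529	OP_R030	TCACRRCACGAGCTGWCGAC	1060	1079	565	V4-V7
panel	bacteria	M	OP_F116	YAACGAGCGCAACCC	1099	1113	KP_R060	GACGGGCGGTGWGTRCA	1390	1406	307	V7-V9
panel	bacteria	L	KP_F048	TACGGRAGGCAGCAG	342	356	OP_R030	TCACRRCACGAGCTGWCGAC	1060	1079	737	V3-V7
panel	bacteria	L	KP_F048	TACGGRAGGCAGCAG	342	356	KP_R060	GACGGGCGGTGWGTRCA	1390	1406	1064	V3-V9
panel	bacteria	L	KP_F056	AYTGGGYDTAAAGNG	572	576	KP_R077	GACGGGCGGTGTGTACAA	1389	1406	834	V4-V9
panel	archaea	S	KP_F018	GYGCASCAGKCGMGAAW	U	U	KP_R002	TTACCGCGGCKGCTG	518	532	U	V4
panel	archaea	S	OP_F066	GGMTTAGATACCC	784	796	KP_R013	GGCCATGCACCWCCTCTC	U	U	U	V5-V6
panel	archaea	M	KP_F018	GYGCASCAGKCGMGAAW	U	U	KP_R032	TACNVGGGTATCTAATCC	784	801	U	V3-V5
panel	archaea	M	KP_F018	GYGCASCAGKCGMGAAW	U	U	OP_R073	CRTACTHCHCAGGYG	879	893	U	V3-V5
panel	archaea	M	KP_F020	CAGCMGCCGCGGTAA	518	532	KP_R013	GGCCATGCACCWCCTCTC	U	U	U	V3-V6
panel	archaea	M	KP_F022	AGGAATTGGCGGGGGAGCA	U	U	KP_R063	TACCTTGTTACGACTT	1491	1506	U	V5-V9
panel	archaea	L	OP_F114	CCTAYGGGRBGCASCAG	340	356	KP_R013	GGCCATGCACCWCCTCTC	U	U	U	V3-V6
panel	archaea	L	KP_F018	GYGCASCAGKCGMGAAW	U	U	KP_R063	TACCTTGTTACGACTT	1491	1506	U	V3-V9
panel	archaea	L	OP_F066	GGMTTAGATACCC	784	796	OP_R016	CGGTGTGTGCAAGGAG	U	U	U	V5-V9
panel	both	S	OP_F114	CCTAYGGGRBGCASCAG	340	356	KP_R002	TTACCGCGGCKGCTG	518	532	192	V3-V4
panel	both	S	KP_F020	CAGCMGCCGCGGTAA	518	532	KP_R032	TACNVGGGTATCTAATCC	784	801	283	V4-V5
panel	both	S	OP_F066	GGMTTAGATACCC	784	796	OP_R073	CRTACTHCHCAGGYG	879	893	109	V5-V6
panel	both	M	OP_F114	CCTAYGGGRBGCASCAG	340	356	KP_R031	TACHVGGGTATCTAAKCC	784	801	461	V3-V5
panel	both	M	OP_F114	CCTAYGGGRBGCASCAG	340	356	OP_R073	CRTACTHCHCAGGYG	879	893	553	V3-V6
panel	both	M	KP_F020	CAGCMGCCGCGGTAA	518	532	OP_R073	CRTACTHCHCAGGYG	879	893	375	V4-V6
panel	both	L	OP_F114	CCTAYGGGRBGCASCAG	340	356	OP_R121	ACGGGCGGTGWGTRC	1391	1405	1065	V3-V9
panel	both	L	KP_F020	CAGCMGCCGCGGTAA	518	532	OP_R121	ACGGGCGGTGWGTRC	1391	1405	887	V4-V9
panel	both	L	OP_F066	GGMTTAGATACCC	784	796	OP_R121	ACGGGCGGTGWGTRC	1391	1405	621	V5-V9
most_used	both	S	KP_F078	GTGCCAGCMGCCGCGGTAA	514	532	OP_R010	GGACTACHVGGGTWTCTAAT	786	805	291	V4-V5
most_used	bacteria	M	KP_F031	AGAGTTTGATCCTGGCTCAG	8	27	KP_R021	TTACCGCGGCTGCTGGCAC	515	532	524	V1-V4
most_used	bacteria	M	KP_F047	CCTACGGGNGGCWGCAG	340	356	KP_R035	GACTACHVGGGTATCTAATCC	784	804	464	V3-V5
most_used	bacteria	M	OP_F009	GGATTAGATACCCBRGTAGTC	784	868	OP_R029	ACGTCRTCCCCDCCTTCCTC	1174	1193	409	V5-V8
most_used	archaea	L	KP_F014	TCCAGGCCCTACGGG	U	U	KP_R011	YCCGGCGTTGAMTCCAATT	U	U	U	V3-V6
most_used	bacteria	L	KP_F034	AGAGTTTGATCMTGGCTCAG	8	27	KP_R065	TACGGYTACCTTGTTACGACTT	1491	1512	1504	V1-V9
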