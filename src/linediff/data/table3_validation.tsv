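chrom	contig	pos	ref_base	called_base	impact	snp_rate	gene_symbol	protein_change	bl_ratio	sl_ratio
2	NC_006089	7746258	C	-	Frameshift	1	LOC100859401	Y129fs	All_C	All_Del
5	NC_006092	21158570	-	A	Frameshift	0.9	LOC770458	A35fs	Ins_A_30%	Ins_A_100%
9	NC_006096	21419266	C	A	N-Syn	0.82	SPTSSB	P15Q	C:A = 3:1	C:A = 1:4
1	NC_006088	54936701	G	T	N-Syn	0.8	STAB2	A2052D	All_G	G:T = 1:1
3	NC_006090	48575253	C	T	N-Syn	0.9	SYNE1	A3892T	C:T = 10:1	C:T = 1:10
3	NC_006090	18177438	T	C	N-Syn	1	EPRS	C315R	T:C = 4:1	T:C = 1:7
1	NC_006088	105941417	T	C	N-Syn	0.9	SETD4	I396V	T:C = 10:1	All_C
19	NC_006106	5858876	T	C	N-Syn	1	ERAL1	M396V	All_T	T:C = 1:10
1	NC_006088	177772554	C	A	N-Syn	0.86	EFHA1	A220D	C:A = 4:1	C:A = 1:10
1	NC_006088	177772568	G	A	N-Syn	0.86	EFHA1	V225I	All_G	G:A = 1:10
13	NC_006100	11337736	C	G	N-Syn	0.9	GEMIN5	H283Q	All_C	All_G
5	NC_006092	44443744	G	G|C	N-Syn	0.75	KIAA1409	Q692H	All_G	G:C = 1:10
5	NC_006092	44443754	G	A	N-Syn	0.8	KIAA1409	E696K	All_G	G:A = 1:4
5	NC_006092	44443755	A	T	N-Syn	0.8	KIAA1409	E696V	All_A	A:T = 1:4
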