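contig	chrom
NC_006088	1
NC_006089	2
NC_006090	3
NC_006091	4
NC_006092	5
NC_006093	6
NC_006094	7
NC_006095	8
NC_006096	9
NC_006097	10
NC_006098	11
NC_006099	12
NC_006100	13
NC_006101	14
NC_006102	15
NC_006103	16
NC_006104	17
NC_006105	18
NC_006106	19
NC_006107	20
NC_006108	21
NC_006109	22
NC_006110	23
NC_006111	24
NC_006112	25
NC_006113	26
NC_006114	27
NC_006115	28
NC_006126	W
NC_006127	Z
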