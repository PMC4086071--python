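##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=16>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	FATHER	MOTHER	PROBAND	SIBLING
1	861332	rs201186828	G	A	.	.	.	GT	0/1	0/0	0/1	0/0
1	985955	rs199476396	G	C	.	.	.	GT	0/1	0/1	1/1	0/1
1	1269554	rs307355	T	C	.	.	.	GT	1/1	0/1	1/1	0/1
16	31120622	.	C	T	.	.	.	GT	0/1	0/1	1/1	0/0
16	31123542	rs11645428	G	A	.	.	.	GT	0/1	0/1	1/1	1/1
16	31126911	rs749670	A	G	.	.	.	GT	./.	0/1	1/1	0/1
16	31131128	rs8062405	G	A	.	.	.	GT	0/1	0/1	0/1	0/0
16	31133190	rs4788406	A	G	.	.	.	GT	0/1	0/1	1/1	0/1
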