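chrom	pos	ref	alt	rs_id	effects	kg_all	kg_eur	kg_asn	kg_afr	kg_amr	esp	phenotypes
1	861332	G	A	rs201186828	SAMD11:ENST00000342066.7:EX2:exon:protein_coding:missense_variant:p.Gly54Asp:0.32:0.11	0.012	0.015	0.009	0.02	0.011	0.014
1	985955	G	C	rs199476396	AGRN:ENST00000379370.6:EX5:exon:protein_coding:missense_variant:p.Gly76Arg:0.04:0.88;AGRN:ENST00000651234.1:FT5:transcript:protein_coding:intron_variant:::	0.03	0.041	0.018	0.052	0.027	0.033	congenital myasthenic syndrome
1	1269554	T	C	rs307355	TAS1R3:ENST00000339381.5:FT1:transcript:protein_coding:upstream_gene_variant:::	0.26	0.22	0.31	0.29	0.24	0.25
16	31120622	C	T		ITGAM:ENST00000287497.9:EX12:exon:protein_coding:missense_variant:p.Arg409Cys:0.01:0.99
16	31123542	G	A	rs11645428	ITGAM:ENST00000287497.9:FT3:transcript:protein_coding:synonymous_variant:p.Leu441=::	0.18	0.2	0.12	0.22	0.17	0.19
16	31126911	A	G	rs749670	ITGAM:ENST00000287497.9:FT8:transcript:protein_coding:intron_variant:::	0.44	0.41	0.47	0.43	0.46	0.42
16	31131128	G	A	rs8062405	ITGAM:ENST00000287497.9:EX30:exon:protein_coding:missense_variant:p.Ala858Thr:0.55:0.02	0.09	0.07	0.13	0.1	0.08	0.085
16	31133190	A	G	rs4788406	ITGAX:ENST00000268296.8:FT2:transcript:protein_coding:3_prime_UTR_variant:::	0.35	0.33	0.38	0.31	0.36	0.34
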