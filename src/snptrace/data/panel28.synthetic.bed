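# Bundled 28-SNP fingerprint demonstration panel.
# Coordinates, alleles and allele frequencies are SYNTHETIC stand-ins
# (small per-chromosome positions so miniature alignment fixtures stay tiny).
# chrom	start(0-based)	end	rsid	ref	alt	af_genome	af_exome
chr1	599	600	rs969273	A	G	0.18	.
chr1	1799	1800	rs12446127	C	T	0.27	.
chr2	599	600	rs16837903	G	A	0.35	.
chr2	1799	1800	rs12644477	T	C	0.42	.
chr3	599	600	rs724710	A	C	0.5	.
chr3	1799	1800	rs2286615	G	T	0.58	.
chr4	599	600	rs2233437	C	A	0.65	.
chr4	1799	1800	rs1642785	A	G	0.73	.
chr5	599	600	rs1055088	C	T	0.82	.
chr5	1799	1800	rs2229974	G	A	0.22	.
chr6	599	600	rs5759408	T	C	0.31	.
chr6	1799	1800	rs10263573	A	C	0.39	.
chr7	599	600	rs1143685	G	T	0.47	.
chr7	1799	1800	rs1985791	C	A	0.55	.
chr8	599	600	rs664982	A	G	0.63	.
chr8	1799	1800	rs1143686	C	T	0.71	.
chr9	599	600	rs2009433	G	A	0.79	.
chr9	1799	1800	rs76433096	T	C	0.25	.
chr10	599	600	rs1143689	A	C	0.33	.
chr10	1799	1800	rs12445580	G	T	0.45	.
chr11	599	600	rs1071644	C	A	0.52	.
chr11	1799	1800	rs11865395	A	G	0.6	.
chr12	599	600	rs1801018	C	T	0.68	.
chr12	1799	1800	rs4889430	G	A	0.76	.
chr13	599	600	rs62218846	T	C	0.2	.
chr13	1799	1800	rs1805419	A	C	0.4	.
chr14	599	600	rs738094	G	T	0.57	.
chr14	1799	1800	rs3747288	C	A	0.7	.
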