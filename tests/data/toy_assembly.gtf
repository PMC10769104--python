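chr1	irtoolkit	transcript	100	1000	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	exon	100	200	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	exon	300	400	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	exon	500	600	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	exon	700	800	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	exon	900	1000	.	+	.	gene_id "fig9g"; transcript_id "t1"; cov "10";
chr1	irtoolkit	transcript	450	1000	.	+	.	gene_id "fig9g"; transcript_id "t2"; cov "6";
chr1	irtoolkit	exon	450	600	.	+	.	gene_id "fig9g"; transcript_id "t2"; cov "6";
chr1	irtoolkit	exon	700	800	.	+	.	gene_id "fig9g"; transcript_id "t2"; cov "6";
chr1	irtoolkit	exon	900	1000	.	+	.	gene_id "fig9g"; transcript_id "t2"; cov "6";
chr1	irtoolkit	transcript	100	850	.	+	.	gene_id "fig9g"; transcript_id "t3"; cov "6";
chr1	irtoolkit	exon	100	200	.	+	.	gene_id "fig9g"; transcript_id "t3"; cov "6";
chr1	irtoolkit	exon	300	400	.	+	.	gene_id "fig9g"; transcript_id "t3"; cov "6";
chr1	irtoolkit	exon	500	600	.	+	.	gene_id "fig9g"; transcript_id "t3"; cov "6";
chr1	irtoolkit	exon	700	850	.	+	.	gene_id "fig9g"; transcript_id "t3"; cov "6";
chr1	irtoolkit	transcript	100	800	.	+	.	gene_id "fig9g"; transcript_id "t4"; cov "6";
chr1	irtoolkit	exon	100	200	.	+	.	gene_id "fig9g"; transcript_id "t4"; cov "6";
chr1	irtoolkit	exon	300	550	.	+	.	gene_id "fig9g"; transcript_id "t4"; cov "6";
chr1	irtoolkit	exon	700	800	.	+	.	gene_id "fig9g"; transcript_id "t4"; cov "6";
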