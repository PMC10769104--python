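chr1	irtoolkit	transcript	20	960	.	+	.	gene_id "T2G1"; transcript_id "T2.A";
chr1	irtoolkit	exon	20	69	.	+	.	gene_id "T2G1"; transcript_id "T2.A";
chr1	irtoolkit	exon	251	609	.	+	.	gene_id "T2G1"; transcript_id "T2.A";
chr1	irtoolkit	exon	731	789	.	+	.	gene_id "T2G1"; transcript_id "T2.A";
chr1	irtoolkit	exon	911	960	.	+	.	gene_id "T2G1"; transcript_id "T2.A";
chr1	irtoolkit	transcript	380	780	.	+	.	gene_id "T2G1"; transcript_id "T2.B";
chr1	irtoolkit	exon	380	429	.	+	.	gene_id "T2G1"; transcript_id "T2.B";
chr1	irtoolkit	exon	731	780	.	+	.	gene_id "T2G1"; transcript_id "T2.B";
chr1	irtoolkit	transcript	2530	2900	.	+	.	gene_id "T2G2"; transcript_id "T2.C";
chr1	irtoolkit	exon	2530	2579	.	+	.	gene_id "T2G2"; transcript_id "T2.C";
chr1	irtoolkit	exon	2611	2789	.	+	.	gene_id "T2G2"; transcript_id "T2.C";
chr1	irtoolkit	exon	2851	2900	.	+	.	gene_id "T2G2"; transcript_id "T2.C";
chr1	irtoolkit	transcript	2530	2660	.	+	.	gene_id "T2G2"; transcript_id "T2.D";
chr1	irtoolkit	exon	2530	2579	.	+	.	gene_id "T2G2"; transcript_id "T2.D";
chr1	irtoolkit	exon	2611	2660	.	+	.	gene_id "T2G2"; transcript_id "T2.D";
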