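chr10	mexquant_synthetic	gene	78030001	78034100	.	+	.	gene_id "RPS24"; gene_name "RPS24";
chr10	mexquant_synthetic	transcript	78030001	78034100	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn";
chr10	mexquant_synthetic	exon	78030001	78030060	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn"; exon_id "ex4";
chr10	mexquant_synthetic	exon	78031001	78031003	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn"; exon_id "m3";
chr10	mexquant_synthetic	exon	78032001	78032018	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn"; exon_id "m18";
chr10	mexquant_synthetic	exon	78033001	78033022	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn"; exon_id "m22";
chr10	mexquant_synthetic	exon	78034001	78034100	.	+	.	gene_id "RPS24"; transcript_id "RPS24-syn"; exon_id "ex6";
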