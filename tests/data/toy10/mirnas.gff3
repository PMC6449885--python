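##gff-version 3
chr1	.	miRNA	1000	1085	.	+	.	ID=A;Name=A
chr1	.	miRNA	12000	12085	.	+	.	ID=B;Name=B
chr2	.	miRNA	5000	5085	.	+	.	ID=C;Name=C
chr1	.	miRNA	200000	200085	.	-	.	ID=D;Name=D
chr3	.	miRNA	1000	1085	.	+	.	ID=E;Name=E
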