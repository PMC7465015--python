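name	chrom	start	end	strand	flank5	tsd	flank3	ecr	method
FGF4L1	chr18	20443703	20443735	+	ACCATGAAAT	AAGTCAGACAGAG	AAAGACAAGT	2	GWAS
FGF4L2	chr12	33710158	33710188	+	ATTCCTATTC	AAGTGCTTTGA	ACTCTTCAAA	1	GWAS
FGF4L3	chr27	24834102	24834135	-	TGAGAATACT	CAGGGACCATTTCT	ATTGACTTTT	0	DRM
FGF4L4	chr22	47761852	47761888	+	TGTCTTTGTC	AAGAATATTCTGGTTGT	GAGTAATAGA	2	DRM
FGF4L5	chr13	28020009	28020044	+	GCAGTTTCTT	AAAACTTAGAGGAACA	AAGTAGCTTG	6	DRM
FGF4L6	chr36	11456175	11456208	+	AAAGCATTAA	TTACCAAAGTACTA	TTTCATAACT	1	DRM
FGF4L7	chr13	25020597	25020632	-	GAATCGTGTT	TAAGAAGGGGTGGTAT	GACTTGCCCT	3	inverse_PCR
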