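name	sequence	anneals
mito_insert_a	GGGTCTCATCTGAAGGGAGGCAGGC	within the mitochondrial-like insert
mito_insert_b	GTGAGGCAGGTTCTCATGGTTCGG	within the mitochondrial-like insert
plastid_flank	GTGCTATCGGATCGGGTGAATTAGAG	in flanking plastid sequence
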