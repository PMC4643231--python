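# Literature-derived universal 16S rRNA primer pairs (editable defaults).
# Coordinates are 1-based inclusive anchor positions on the E. coli 16S
# reference numbering: ecoli_start = first base of the forward site,
# ecoli_stop = last base of the reverse site (primer-inclusive).
name	region	forward_name	forward_seq	reverse_name	reverse_seq	ecoli_start	ecoli_stop
U341F/534R	V3	U341F	CCTACGGGAGGCAGCAG	534R	ATTACCGCGGCTGCTGG	341	534
515F/806R	V4	515F	GTGCCAGCMGCCGCGGTAA	806R	GGACTACHVGGGTWTCTAAT	515	806
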