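# Two-amplicon panel over a 3'UTR CpG cluster (placeholder coordinates,
# realistic spacing: 9 sparse CpGs then 6 denser CpGs).
chr1	11082200	11082450	utr_cpg_1_9	0	+
chr1	11082475	11082700	utr_cpg_10_15	0	+
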