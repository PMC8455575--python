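# 0-based CpG cytosine offsets within each amplicon read.
region_id	cpg_offsets
utr_cpg_1_9	18,45,71,98,122,150,177,203,231
utr_cpg_10_15	12,30,41,77,102,130
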