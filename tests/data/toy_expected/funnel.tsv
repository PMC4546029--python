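stage	count
input	53
removed_haplotype	2
removed_gap	2
removed_mismatch	2
removed_numt	2
unspliced_ests	45
clusters	11
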