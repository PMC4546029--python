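cluster_id	evidence	host_genes	orientation
uc000002	cage	gA_chrA1_000	forward
uc000002	chromatin	gA_chrA1_000	none
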