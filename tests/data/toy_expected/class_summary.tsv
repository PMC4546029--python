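class	n_clusters
TEX	1
TIN	1
5PIN	1
3PIN	1
rI	1
5R	1
3R	1
UT	1
DT	1
IGR	1
NO_CLASS	1
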