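cluster_a	cluster_b	detected_by	same_class
uc000001	uc000001	both	True
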