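chrA1	7500	7700	uc000001	5	.
chrA1	9850	10100	uc000002	4	.
chrA1	11850	12350	uc000003	3	.
chrA1	14150	15750	uc000004	3	.
chrA1	16750	16950	uc000005	5	.
chrA1	17700	17900	uc000006	4	.
chrA1	17950	18150	uc000007	6	.
chrA1	19350	19550	uc000008	3	.
chrA1	19800	20050	uc000009	3	.
chrA1	22200	22400	uc000010	4	.
chrA1	30000	30200	uc000011	5	.
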