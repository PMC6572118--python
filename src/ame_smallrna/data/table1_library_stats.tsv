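type	total	pct_total	distinct	pct_distinct
Raw reads	9685427	100.00	3697922	100.00
3ADT & length filter	3020110	31.18	949768	25.68
Junk reads	58185	0.60	48416	1.31
Rfam	840690	8.68	100245	2.71
Repeats	5584	0.06	1321	0.04
Clean reads	5761893	59.49	2598545	70.27
rRNA	625393	6.46	59659	0.62
tRNA	160729	1.66	29496	0.30
snoRNA	5296	0.05	1977	0.02
snRNA	7931	0.08	3860	0.04
Other Rfam RNA	41341	0.43	5253	0.05
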