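member	Cre	Ppa	Smo	Atr	Vvi	Ptr	Cpa	Ath	Bra
SnRK2.1	0	0	0	0	0	0	0	1	3
SnRK2.2	0	0	0	0	0	0	0	1	1
SnRK2.3	0	0	0	0	1	1	1	1	1
SnRK2.4	0	0	0	1	1	2	1	1	2
SnRK2.5	0	0	0	0	1	2	1	1	1
SnRK2.6	1	1	1	1	1	2	1	1	2
SnRK2.7	0	0	0	0	1	1	1	1	1
SnRK2.8	0	0	0	1	1	1	1	1	2
SnRK2.9	0	0	0	0	0	0	0	1	1
SnRK2.10	0	0	0	0	1	1	1	1	1
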