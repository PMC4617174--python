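Gene name	Acc ID	DNA(bp)	CDS(bp)	Intron	Size(aa)	Mass(Kda)	IP	Subcellular localization
BcSnRK2.1a	KT236157	2441	1368	9	455	51.93	5.43	Nuclear
BcSnRK2.1b	KT236158	2113	1095	8	364	41.71	6.04	Nuclear
BcSnRK2.2	KT236159	1780	1086	7	361	41.00	4.46	Nuclear
BcSnRK2.3	KT236160	1786	1089	7	362	41.07	4.55	Nuclear
BcSnRK2.4a	KT236161	1678	1011	7	336	38.00	5.24	Cytoplasmic
BcSnRK2.4b	KT236162	2004	1065	8	354	40.39	6.20	Cytoplasmic
BcSnRK2.5	KT236163	1636	1077	7	358	41.16	5.09	Nuclear
BcSnRK2.6a	KT236164	2095	1086	9	361	40.88	4.69	Nuclear-Cytoplasmic
BcSnRK2.6b	KT236165	2000	1089	9	362	40.91	4.59	Nuclear
BcSnRK2.7	KT236166	2465	1044	8	347	39.39	4.64	Cytoplasmic
BcSnRK2.8a	KT236167	1670	1029	5	342	38.15	5.44	Nuclear-Cytoplasmic
BcSnRK2.8b	KT236168	2640	1029	6	342	38.07	5.62	Nuclear-Cytoplasmic
BcSnRK2.10	KT236169	2384	1059	8	352	40.22	6.36	Cytoplasmic
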