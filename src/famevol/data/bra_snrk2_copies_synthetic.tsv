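ancestral_id	copy_id	subgenome	chrom	position
SnRK2.1	BraSnRK2.1-LF	LF	Chr5	1
SnRK2.1	BraSnRK2.1-MF1	MF1	Chr5	1
SnRK2.1	BraSnRK2.1-MF2	MF2	Chr5	1
SnRK2.2	BraSnRK2.2-LF	LF	Chr3	1
SnRK2.3	BraSnRK2.3-LF	LF	Chr5	3
SnRK2.4	BraSnRK2.4-LF	LF	Chr1	1
SnRK2.4	BraSnRK2.4-MF1	MF1	Chr1	1
SnRK2.5	BraSnRK2.5-LF	LF	Chr5	2
SnRK2.6	BraSnRK2.6-LF	LF	Chr4	1
SnRK2.6	BraSnRK2.6-MF1	MF1	Chr4	1
SnRK2.7	BraSnRK2.7-MF1	MF1	Chr4	2
SnRK2.8	BraSnRK2.8-LF	LF	Chr1	3
SnRK2.8	BraSnRK2.8-MF2	MF2	Chr1	3
SnRK2.9	BraSnRK2.9-LF	LF	Chr2	1
SnRK2.10	BraSnRK2.10-MF2	MF2	Chr1	2
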