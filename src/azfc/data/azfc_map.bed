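chrY	23000000	23450000	Gr1	Gr	+
chrY	23450000	23560000	b1	b	+
chrY	23560000	23890000	t1	t	+
chrY	23890000	24040000	P3_spacer	spacer	+
chrY	24040000	24370000	t2	t	+
chrY	24370000	24480000	b2	b	-
chrY	24480000	24550000	IR1	unique	+
chrY	24550000	24750000	g1	g	+
chrY	24750000	24900000	r1	r	+
chrY	24900000	25050000	r2	r	+
chrY	25050000	25160000	b3	b	+
chrY	25160000	26165000	y1	y	+
chrY	26165000	26365000	g2	g	+
chrY	26365000	26515000	r3	r	+
chrY	26515000	26665000	r4	r	+
chrY	26665000	26865000	g3	g	+
chrY	26865000	27870000	y2	y	+
chrY	27870000	27980000	b4	b	-
chrY	27980000	28430000	Gr2	Gr	+
chrY	14500000	15500000	single_copy_norm	norm	+
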