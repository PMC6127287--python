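pair	role	position	sequence	product_size	note
L1	forward	13f	TGGCTCAGGAYGAACGCYG	~1000	.
L1	reverse	957r	TCGAATTAAACCACATGCTCCA	~1000	.
L2	forward	13f	TGGCTCAGGAYGAACGC	~1000	.
L2	reverse	957r	GAGGCWGCAGTAGGGAATC	~1000	.
L3	forward	361f	TCCGGAWTTATTGGGCGTAAAG	~600	.
L3	reverse	957r	TCGAATTAAACCACATGCTCCA	~600	.
L4	forward	567f	TCGAATTAAACCACATGCTCCA	~400	suspect_duplicate
L4	reverse	957r	TCGAATTAAACCACATGCTCCA	~400	.
L5	forward	15f	GCTCAGGAYGAACGCYGG	~750	.
L5	reverse	687r	CACCGCTACACATGRADTTC	~750	.
L6	forward	19f	AGGAYGAACGCYGGCGGCGTGCC	~1000	.
L6	reverse	957r	TCGAATTAAACCACATGCTCCA	~1000	.
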