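# TATA-box / TBP-site base-count matrix, 15 positions, compiled from
# canonical TATA-box alignments of eukaryotic pol II promoters
# (consensus ~ sTATAaAwr followed by a G/C-rich downstream shoulder).
# Converted to log-odds at load time (pseudocount 0.5, uniform background).
pos	A	C	G	T
1	61	145	152	31
2	16	46	18	309
3	352	0	2	35
4	3	10	2	374
5	354	0	5	30
6	268	0	0	121
7	360	3	20	6
8	222	2	44	121
9	155	44	157	33
10	56	135	150	48
11	83	147	128	31
12	82	127	128	52
13	82	118	128	61
14	68	107	139	75
15	77	101	140	71
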