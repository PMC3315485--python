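selected_against	residues_42_45_46	tet20	tet30	total	codons
GCA	RQR	2	3	5	1
GCA	RGR	1	3	4	1
GCA	RLR	2	1	3	2
GCA	RTR	1	0	1	1
GCA	GSR	3	1	4	2
GCA	GQR	1	1	2	2
GCA	GGR	1	0	1	1
GCA	WQR	1	0	1	1
GCA	WMR	2	0	2	1
GCA	TSR	1	0	1	1
GCA	TCK	1	0	1	1
GCA	SCR	1	0	1	1
GCA	FMR	1	0	1	1
GAA	SAR	1	0	1	1
GAA	SQR	15	15	30	3
GAC	RCR	3	0	3	1
GAC	RQR	13	0	12	1
GAC	TRR	2	0	2	1
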