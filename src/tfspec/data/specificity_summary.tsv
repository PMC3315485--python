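variant	dg_ns_kj_mol	rseq_energy_bits	rseq_invivo_bits	rseq_over_dgns	confident
WQR	2.70	3.03	3.26	1.21	yes
RQR	4.46	2.27	2.17	0.49	yes
RTR	3.30	2.46	2.52	0.76	yes
SAR	-9.98	0.80	4.66	-0.47	no
TRR	2.40	2.44	6.00	2.5	yes
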