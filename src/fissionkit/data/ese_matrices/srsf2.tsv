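pos	A	C	G	T
1	0.21	1.05	0.42	-1.04
2	1.12	-0.52	0.33	-1.21
3	0.08	-0.81	1.18	-1.02
4	0.30	1.47	0.24	-1.48
5	1.05	-0.63	0.58	-1.13
6	0.18	-0.74	1.22	-1.27
7	0.83	0.12	0.41	-0.92
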