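pos	A	C	G	T
1	0.45	-0.70	1.10	-1.10
2	0.52	-0.95	1.15	-1.05
3	1.20	-0.80	0.30	-1.15
4	1.08	-0.73	0.62	-1.02
5	0.58	-0.66	1.12	-1.20
6	1.16	-0.92	0.40	-1.01
7	0.95	-0.60	0.55	-0.85
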