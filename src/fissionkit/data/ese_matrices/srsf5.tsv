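pos	A	C	G	T
1	0.35	0.10	-0.90	0.85
2	-0.40	1.10	0.25	-0.95
3	1.15	-0.55	0.30	-1.05
4	0.15	1.20	-0.62	-1.10
5	1.05	-0.58	0.48	-0.98
6	0.22	-0.75	1.18	-1.12
7	0.38	-0.44	0.92	-0.80
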