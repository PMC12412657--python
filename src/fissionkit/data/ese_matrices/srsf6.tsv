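pos	A	C	G	T
1	-0.55	0.30	-0.20	0.90
2	-0.60	0.25	1.05	-0.35
3	-0.70	1.10	0.20	-0.45
4	-0.80	0.15	1.12	-0.25
5	-0.50	0.35	-0.30	1.00
6	-0.65	1.02	0.28	-0.15
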