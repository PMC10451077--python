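# miniature synthetic haplogroup-marker table (tests only)
haplogroup	position	alt	frequency
H2a	263	G	99.0
H2a	750	G	99.0
H2a	1438	G	98.0
H2a	4769	G	97.0
H2a	8860	G	99.0
H2a	15326	G	99.0
H2a	16189	C	62.0
D4	3010	A	95.0
D4	4883	T	96.0
D4	5178	A	97.0
D4	8414	T	92.0
D4	14668	T	90.0
D4	9824	G	80.0
D4	12705	T	79.9
B4a	499	A	93.0
B4a	827	G	91.0
B4a	13590	A	88.0
B4a	15535	T	85.0
B4a	16217	G	90.0
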