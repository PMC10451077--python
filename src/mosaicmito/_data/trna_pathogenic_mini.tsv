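# miniature pathogenic-tRNA table (tests only)
position	alt	classification
3243	G	confirmed
3271	C	confirmed
4269	G	confirmed
8344	A	confirmed
8356	C	confirmed
1630	G	likely
5728	G	likely
12147	A	likely
15990	C	likely
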