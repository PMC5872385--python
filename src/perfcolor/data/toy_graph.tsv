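#source	sign	target	weight
B	+1	D	1
C	+1	D	1
D	+1	E	1
D	+1	F	1
G	+1	H	1
I	+1	G	1
F	-1	G	1
D	-1	H	1
G	-1	A	1
H	-1	A	1
I	-1	G	1
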