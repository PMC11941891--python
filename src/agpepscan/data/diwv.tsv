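# Dipeptide instability weight values (DIWV) of Guruprasad, Reddy & Pandit (1990),
# Protein Engineering 4:155-161.  Row = first residue, column = second residue.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	1	44.94	-7.49	1	1	1	-7.49	1	1	1	1	1	20.26	1	1	1	1	1	1	1
C	1	1	20.26	1	1	1	33.6	1	1	20.26	33.6	1	20.26	-6.54	1	1	33.6	-6.54	24.68	1
D	1	1	1	1	-6.54	1	1	1	-7.49	1	1	1	1	1	-6.54	20.26	-14.03	1	1	1
E	1	44.94	20.26	33.6	1	1	-6.54	20.26	1	1	1	1	20.26	20.26	1	20.26	1	1	-14.03	1
F	1	1	13.34	1	1	1	1	1	-14.03	1	1	1	20.26	1	1	1	1	1	1	33.601
G	-7.49	1	1	-6.54	1	13.34	1	-7.49	-7.49	1	1	-7.49	1	1	1	1	-7.49	1	13.34	-7.49
H	1	1	1	1	-9.37	-9.37	1	44.94	24.68	1	1	24.68	-1.88	1	1	1	-6.54	1	-1.88	44.94
I	1	1	1	44.94	1	1	13.34	1	-7.49	20.26	1	1	-1.88	1	1	1	1	-7.49	1	1
K	1	1	1	1	1	-7.49	1	-7.49	1	-7.49	33.6	1	-6.54	24.64	33.6	1	1	-7.49	1	1
L	1	1	1	1	1	1	1	1	-7.49	1	1	1	20.26	33.6	20.26	1	1	1	24.68	1
M	13.34	1	1	1	1	1	58.28	1	1	1	-1.88	1	44.94	-6.54	-6.54	44.94	-1.88	1	1	24.68
N	1	-1.88	1	1	-14.03	-14.03	1	44.94	24.68	1	1	1	-1.88	-6.54	1	1	-7.49	1	-9.37	1
P	20.26	-6.54	-6.54	18.38	20.26	1	1	1	1	1	-6.54	1	20.26	20.26	-6.54	20.26	1	20.26	-1.88	1
Q	1	-6.54	20.26	20.26	-6.54	1	1	1	1	1	1	1	20.26	20.26	1	44.94	1	-6.54	1	-6.54
R	1	1	1	1	1	-7.49	20.26	1	1	1	1	13.34	20.26	20.26	58.28	44.94	1	1	58.28	-6.54
S	1	33.6	1	20.26	1	1	1	1	1	1	1	1	44.94	20.26	20.26	20.26	1	1	1	1
T	1	1	1	20.26	13.34	-7.49	1	1	1	1	1	-14.03	1	-6.54	1	1	1	1	-14.03	1
V	1	1	-14.03	1	1	-7.49	1	1	-1.88	1	1	1	20.26	1	1	1	-7.49	1	1	-6.54
W	-14.03	1	1	1	1	-9.37	24.68	1	1	13.34	24.68	13.34	1	1	1	1	-14.03	-7.49	1	1
Y	24.68	1	24.68	-6.54	1	-7.49	13.34	1	1	1	44.94	1	13.34	1	-15.91	1	-7.49	1	-9.37	13.34
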