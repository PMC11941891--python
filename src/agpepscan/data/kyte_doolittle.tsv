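# Kyte-Doolittle hydropathy index (J Mol Biol 1982, 157:105-132).
# Used by the heuristic signal-peptide / GPI stand-ins. X scores 0.
I	4.5
V	4.2
L	3.8
F	2.8
C	2.5
M	1.9
A	1.8
G	-0.4
T	-0.7
S	-0.8
W	-0.9
Y	-1.3
P	-1.6
H	-3.2
E	-3.5
Q	-3.5
D	-3.5
N	-3.5
K	-3.9
R	-4.5
X	0.0
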