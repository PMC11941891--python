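# Ionizable-group pKa sets for net-charge / isoelectric-point computation.
# set	group	pka
# Groups: Nterm, Cterm and the ionizable side chains K, R, H (basic),
# D, E, C, Y (acidic).  "expasy" follows the Bjellqvist convention used by
# the ExPASy/ProtParam family of tools (single N-terminal value);
# "emboss" follows the EMBOSS iep defaults.
expasy	Nterm	7.50
expasy	Cterm	3.55
expasy	K	10.00
expasy	R	12.00
expasy	H	5.98
expasy	D	4.05
expasy	E	4.45
expasy	C	9.00
expasy	Y	10.00
emboss	Nterm	8.60
emboss	Cterm	3.60
emboss	K	10.80
emboss	R	12.50
emboss	H	6.50
emboss	D	3.90
emboss	E	4.10
emboss	C	8.50
emboss	Y	10.10
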