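# Default cis-regulatory element table for promoter scanning.
# Curated approximation of common PlantCARE element consensi; edit freely.
# Columns: name, IUPAC consensus, functional category
# Categories: light, stress, growth, hormone
name	consensus	category
G-box	CACGTG	light
Box4	ATTAAT	light
GT1-motif	GGTTAA	light
TCT-motif	TCTTTA	light
Sp1	GGGCGG	light
MRE	AACCTAA	light
I-box	GATAAGR	light
GATA-motif	AAGGATAAGG	light
AE-box	AGAAACAA	light
ACE	ACGTGGA	light
LAMP-element	CTTTATCA	light
ARE	AAACCA	stress
WUN-motif	AAATTTCCT	stress
MBS	CAACTG	stress
DRE-core	GCCGAC	stress
LTR	CCGAAA	stress
TC-rich-repeats	GTTTTCTTAC	stress
STRE	AGGGG	stress
W-box	TTGACC	stress
CAT-box	GCCACT	growth
CCGTCC-box	CCGTCC	growth
circadian	CAANNNNATC	growth
O2-site	GATGACATGG	growth
RY-element	CATGCATG	growth
ABRE	ACGTG	hormone
TCA-element	CCATCTTTTT	hormone
AAGAA-motif	GAAAGAA	hormone
TGA-element	AACGAC	hormone
AuxRR-core	GGTCCAT	hormone
P-box	CCTTTTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
ERE	ATTTTAAA	hormone
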