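gene	category	pathway
ACD	high	telomere
TPP1	high	telomere
BAP1	high	cell_cycle
CDKN2A	low_and_high	cell_cycle
CDK4	high	cell_cycle
POT1	high	telomere
TERF2IP	high	telomere
IRF4	intermediate	pigmentation
MC1R	intermediate	pigmentation
MITF	intermediate	melanocyte_differentiation
SLC45A2	intermediate	pigmentation
AGR3	low	unknown
ARNT	low	xenobiotic_metabolism
ASIP	low	pigmentation
ATM	low	dna_repair
CASP8	low	apoptosis
CCND1	low	cell_cycle
CDKAL1	low	unknown
CDKN2B	low	cell_cycle
FTO	low	dna_repair
HERC2	low	pigmentation
KITLG	low	pigmentation
MTAP	low	9p21.3_locus
MX2	low	unknown
OBFC1	low	telomere
OCA2	low	pigmentation
PARP1	low	dna_repair
PLA2G6	low	nevi
SLC24A5	low	pigmentation
TERT	low_and_high	telomere_nevi
CLPTM1L	low_and_high	telomere_nevi
RAD23B	low	dna_repair
TMEM38B	low	dna_repair
TYR	low	pigmentation
TYRP1	low	pigmentation
BRAF	driver	driver
NRAS	driver	driver
HRAS	driver	driver
NF1	driver	driver
RAC1	driver	driver
MAP2K1	driver	driver
TP53	driver	driver
ARID2	driver	driver
DDX3X	driver	driver
PPP6C	driver	driver
PTEN	driver	driver
RB1	driver	driver
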