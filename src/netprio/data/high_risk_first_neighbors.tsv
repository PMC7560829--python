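seed	partner	partner_is_candidate
ACD	TERT	0
ACD	OBFC1	0
ACD	POT1	0
ACD	TERF1	0
ACD	TERF2IP	0
TPP1	POT1	0
TPP1	TERT	0
BAP1	PTEN	0
CDKN2A	GGA3	1
CDKN2A	ATR	1
CDKN2A	CCND1	0
CDKN2A	CDK4	0
CDKN2A	CDK6	0
CDKN2A	EIF3A	1
CDKN2A	HRAS	0
CDKN2A	MAP2K1	0
CDKN2A	TP53	0
CDK4	CDKN2A	0
CDK4	CCND1	0
CDK4	CDKN2B	1
CDK4	PKM	1
CDK4	RB1	0
CDK4	CDK6	0
POT1	ACD	0
POT1	DDX3X	0
POT1	PROSER2	1
POT1	IL1RN	1
POT1	PRKDC	1
POT1	TERF2IP	0
POT1	ECI1	1
POT1	CYP4F11	1
POT1	OBFC1	0
POT1	TPP1	0
POT1	TERT	0
POT1	TERF1	0
TERF2IP	DDX24	1
TERF2IP	FABP2	1
TERF2IP	IL1RN	1
TERF2IP	ACD	0
TERF2IP	OBFC1	0
TERF2IP	PARP1	0
TERF2IP	TERF1	0
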