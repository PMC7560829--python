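family_id	gene	chrom	pos	ref	alt	consequence	maf_1kg	maf_esp	maf_exac	inhouse_family_count	carriers_in_family	cases_sequenced	metasvm	metalr	cadd	qc_flagged	depth	abhet	caller_count
F1	GENEA	1	1000	A	G	missense	0.0001	.	.	0	3	5	D	D	25.0	0	45	0.52	3
F1	GENEB	2	2000	C	T	stop_gain	.	.	.	2	3	5	.	.	.	0	60	0.48	3
F2	GENEC	3	3000	G	A	splicing	0.0005	0.0002	0.0004	1	4	4	.	.	.	0	38	0.55	2
F2	GENEA	1	1005	T	C	missense	.	0.0003	.	1	3	4	D	T	30.0	0	52	0.47	3
F3	GENED	4	4000	AT	A	frameshift	.	.	.	0	5	5	.	.	.	0	70	.	3
F3	GENEE	5	5000	C	G	missense	0.0002	.	0.0001	2	3	5	T	D	22.0	0	33	0.6	2
F4	GENEF	6	6000	G	GAA	inframe_indel	.	.	.	1	3	5	.	.	.	0	41	.	2
F1	GENEG	7	7000	A	C	missense	.	.	0.002	0	3	5	D	D	25.0	0	50	0.5	3
F2	GENEH	8	8000	C	A	stop_gain	.	.	.	3	3	4	.	.	.	0	44	0.51	3
F3	GENEI	9	9000	G	GT	frameshift	0.0001	.	.	1	2	5	.	.	.	0	39	0.45	3
F4	GENEJ	10	10000	T	C	other	.	.	0.0002	0	4	5	.	.	.	0	55	0.5	3
F4	MUC16	11	11000	G	T	missense	.	.	.	0	3	5	D	D	30.0	0	48	0.49	3
F5	GENEK	12	12000	A	G	missense	0.0003	.	.	1	3	3	T	T	15.0	0	36	0.42	2
F5	GENEL	13	13000	C	T	splicing	.	0.0001	.	0	3	3	.	.	.	0	8	0.5	3
F5	GENEM	14	14000	G	A	missense	.	.	0.0004	2	3	3	T	T	24.0	0	42	0.53	3
F6	GENEN	15	15000	T	G	missense	0.0002	.	.	0	3	4	D	D	27.0	0	51	0.85	3
F6	GENEO	16	16000	C	G	stop_gain	.	.	.	1	4	4	.	.	.	0	47	0.5	1
F6	GENEP	17	17000	A	T	missense	.	0.0005	.	0	3	4	D	D	29.0	1	49	0.5	3
F7	GENEQ	18	18000	G	C	other	0.05	0.04	0.06	4	1	3	.	.	.	0	12	0.5	2
F7	GENER	19	19000	T	A	missense	0.0009	.	.	5	2	3	D	D	21.0	0	55	0.5	3
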