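accession	length	conc_acl	conc_pt	sex_fc_acl	sex_fc_pt	is_standard
CO1A1_HUMAN	1000	200	400	0.833	0.833	False
CO1A2_HUMAN	1000	100	200	0.81	0.89	False
CO2A1_HUMAN	900	4	4	1	1	False
CO3A1_HUMAN	1000	154	48	1	1.2	False
CO5A1_HUMAN	1000	6	3	1	1	False
CO5A2_HUMAN	1000	4	0	1	1	False
CO6A1_HUMAN	900	4	3	1	1.41	False
CO6A2_HUMAN	900	2	1.5	1	1	False
CO6A3_HUMAN	2000	12	6	1	1	False
CO8A1_HUMAN	600	0	1.5	1	1	False
COCA1_HUMAN	1800	1.5	9	1	1	False
COEA1_HUMAN	1600	2	0	1	1	False
COGA1_HUMAN	1400	0.8	0	1	1	False
COLA1_HUMAN	900	0.6	0	1	1	False
PGS1_HUMAN	370	15	5	1	1.3	False
PGS2_HUMAN	360	30	27	0.82	1	False
LUM_HUMAN	340	10	5	1	1.81	False
FMOD_HUMAN	380	4	12	1	1	False
MIME_HUMAN	300	9	2	1	1.31	False
ASPN_HUMAN	380	5	1.5	1	1	False
PRELP_HUMAN	380	8	4	1	1	False
PGCA_HUMAN	2000	1.5	0	1	1	False
CSPG2_HUMAN	2000	1	0	1	1	False
PRG4_HUMAN	1400	3	1.5	1.3	1.3	False
PGBM_HUMAN	2000	1.2	0.5	1	1	False
FINC_HUMAN	1200	8	1.3	1	1	False
TENX_HUMAN	1800	1.75	0.5	1	1	False
TENA_HUMAN	1200	1	0.33	1	1	False
TSP1_HUMAN	1170	0.75	0.75	1	0.49	False
TSP4_HUMAN	960	2.5	1	1	1	False
COMP_HUMAN	760	10	6	1	1	False
CILP1_HUMAN	1180	6	2.5	1	1	False
ELN_HUMAN	750	3	1.2	1	1	False
FBN1_HUMAN	2000	3	4.8	1	1	False
CLUS_HUMAN	450	3	0.85	0.8	0.8	False
BGH3_HUMAN	680	2.5	0.8	1	1	False
POSTN_HUMAN	840	1.5	1.5	1	1	False
MMP3_HUMAN	480	0	0.8	1	0.47	False
TIMP3_HUMAN	210	0.5	0.5	1	1	False
HRG_HUMAN	520	1.2	0.25	1	1	False
A1AT_HUMAN	420	1.5	0.85	1	1	False
AMBP_HUMAN	350	2.5	10	1	1	False
ANXA1_HUMAN	350	1.5	0.5	1	1	False
ANXA2_HUMAN	340	1.2	0.85	1	1.56	False
ANXA5_HUMAN	320	1.5	0.5	1	1	False
CTGF_HUMAN	350	0.8	0.4	1	1	False
ALBU_HUMAN	580	10	6	2.24	2.48	False
TTHY_HUMAN	130	3	2	1	1.83	False
CO9_HUMAN	540	1.8	0.6	0.22	1	False
ADH1B_HUMAN	370	0.6	0.3	0.2	0.12	False
MYOC_HUMAN	500	2	1	3.88	1.2	False
VIME_HUMAN	460	2	1	1	2.01	False
ACTH_HUMAN	370	2	2	1	1.76	False
H4_HUMAN	100	1	2.2	1	1	False
ADH1_YEAST	347	25	25	1	1	True
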