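accession	gene	description	category	blood_related
CO1A1_HUMAN	COL1A1	Collagen alpha-1(I) chain	collagen	False
CO1A2_HUMAN	COL1A2	Collagen alpha-2(I) chain	collagen	False
CO2A1_HUMAN	COL2A1	Collagen alpha-1(II) chain	collagen	False
CO3A1_HUMAN	COL3A1	Collagen alpha-1(III) chain	collagen	False
CO5A1_HUMAN	COL5A1	Collagen alpha-1(V) chain	collagen	False
CO5A2_HUMAN	COL5A2	Collagen alpha-2(V) chain	collagen	False
CO6A1_HUMAN	COL6A1	Collagen alpha-1(VI) chain	collagen	False
CO6A2_HUMAN	COL6A2	Collagen alpha-2(VI) chain	collagen	False
CO6A3_HUMAN	COL6A3	Collagen alpha-3(VI) chain	collagen	False
CO8A1_HUMAN	COL8A1	Collagen alpha-1(VIII) chain	collagen	False
COCA1_HUMAN	COL12A1	Collagen alpha-1(XII) chain	collagen	False
COEA1_HUMAN	COL14A1	Collagen alpha-1(XIV) chain	collagen	False
COGA1_HUMAN	COL16A1	Collagen alpha-1(XVI) chain	collagen	False
COLA1_HUMAN	COL21A1	Collagen alpha-1(XXI) chain	collagen	False
PGS1_HUMAN	BGN	Biglycan	proteoglycan	False
PGS2_HUMAN	DCN	Decorin	proteoglycan	False
LUM_HUMAN	LUM	Lumican	proteoglycan	False
FMOD_HUMAN	FMOD	Fibromodulin	proteoglycan	False
MIME_HUMAN	OGN	Mimecan	proteoglycan	False
ASPN_HUMAN	ASPN	Asporin	proteoglycan	False
PRELP_HUMAN	PRELP	Prolargin	proteoglycan	False
PGCA_HUMAN	ACAN	Aggrecan core protein	proteoglycan	False
CSPG2_HUMAN	VCAN	Versican core protein	proteoglycan	False
PRG4_HUMAN	PRG4	Proteoglycan 4 (lubricin)	proteoglycan	False
PGBM_HUMAN	HSPG2	Basement membrane-specific heparan sulfate proteoglycan	proteoglycan	False
FINC_HUMAN	FN1	Fibronectin	glycoprotein	True
TENX_HUMAN	TNXB	Tenascin-X	glycoprotein	False
TENA_HUMAN	TNC	Tenascin-C	glycoprotein	False
TSP1_HUMAN	THBS1	Thrombospondin-1	glycoprotein	False
TSP4_HUMAN	THBS4	Thrombospondin-4	glycoprotein	False
COMP_HUMAN	COMP	Cartilage oligomeric matrix protein	glycoprotein	False
CILP1_HUMAN	CILP	Cartilage intermediate layer protein 1	glycoprotein	False
ELN_HUMAN	ELN	Elastin	glycoprotein	False
FBN1_HUMAN	FBN1	Fibrillin-1	glycoprotein	False
CLUS_HUMAN	CLU	Clusterin	glycoprotein	True
BGH3_HUMAN	TGFBI	Transforming growth factor-beta-induced protein ig-h3	glycoprotein	False
POSTN_HUMAN	POSTN	Periostin	glycoprotein	False
MMP3_HUMAN	MMP3	Stromelysin-1	ECM_regulator	False
TIMP3_HUMAN	TIMP3	Metalloproteinase inhibitor 3	ECM_regulator	False
HRG_HUMAN	HRG	Histidine-rich glycoprotein	ECM_regulator	True
A1AT_HUMAN	SERPINA1	Alpha-1-antitrypsin	ECM_regulator	True
AMBP_HUMAN	AMBP	Protein AMBP	ECM_regulator	True
ANXA1_HUMAN	ANXA1	Annexin A1	ECM_affiliated	False
ANXA2_HUMAN	ANXA2	Annexin A2	ECM_affiliated	False
ANXA5_HUMAN	ANXA5	Annexin A5	ECM_affiliated	False
CTGF_HUMAN	CCN2	Cellular communication network factor 2	secreted_factor	False
ALBU_HUMAN	ALB	Serum albumin	non_matrisome	True
TTHY_HUMAN	TTR	Transthyretin	non_matrisome	True
CO9_HUMAN	C9	Complement component C9	non_matrisome	True
ADH1B_HUMAN	ADH1B	Alcohol dehydrogenase 1B	non_matrisome	False
MYOC_HUMAN	MYOC	Myocilin	non_matrisome	False
VIME_HUMAN	VIM	Vimentin	non_matrisome	False
ACTH_HUMAN	ACTG2	Actin, gamma-enteric smooth muscle	non_matrisome	False
H4_HUMAN	HIST1H4A	Histone H4	non_matrisome	False
ADH1_YEAST	ADH1	Alcohol dehydrogenase 1 (spiked surrogate standard)	non_matrisome	False
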