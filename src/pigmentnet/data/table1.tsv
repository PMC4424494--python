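Node A	Node B	Interaction type A->B
UVA	Lipid_Peroxidation_kerat	induces
Lipid_Peroxidation_kerat	4HNE_kerat	increases level
4HNE_kerat	DNA_Damage_kerat	induces
DNA_Damage_kerat	TP53_kerat	activates
TP53_kerat	ACTH_kerat	increases expression
TP53_kerat	alpha_MSH_kerat	increases expression
ACTH_kerat	MC1R_melan	activates
alpha_MSH_kerat	MC1R_melan	activates
MC1R_melan	ADCY4_melan	activates
ADCY4_melan	cAMP_melan	increases level
CREB1_melan	PTGS2_melan	increases expression
PGE2_kerat	PTGER3_melan	activates
PGE2_kerat	PTGER1_melan	activates
PTGER3_melan	PLC_melan	activates
PTGER1_melan	PLC_melan	activates
PLC_melan	DAG_melan	increases level
DAG_melan	PRKCB_melan	activates
PTGS2_melan	PGE2_melan	Increases level
PRKCB_melan	TYR_melan	activates
TYR_melan	Eumelanin_melan	Increases level
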