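table	process	role	perturbed	path
3	melanogenesis_tyr_activation	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PLA2_kerat- > Arachidonic_Acid_kerat- > PGE2_kerat- > PTGER3_melan- > PLC_melan- > DAG_melan- > PRKCB_melan- > TYR_melan- > Eumelanin_melan
3	melanogenesis_tyr_activation	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PLA2_kerat- > Arachidonic_Acid_kerat- > PGE2_kerat- > PTGER3_melan- > PLC_melan- > DAG_melan- > PRKCB_melan- > TYR_melan- > Pheomelanin_melan
3	ptgs2_induction	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > PTGS2_kerat
3	melanogenesis_tyr_expression	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > KITLG_kerat- > KIT_melan- > PIK3CA_melan- > PDPK1_melan- > AKT1_melan- > CREB1_melan- > MITF_melan- > TYR_melan- > Eumelanin_melan
3	melanogenesis_tyr_expression	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > KITLG_kerat- > KIT_melan- > PIK3CA_melan- > PDPK1_melan- > AKT1_melan- > CREB1_melan- > MITF_melan- > TYR_melan- > Pheomelanin_melan
3	melanogenesis_no_cgmp	predicted		UVA- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > NOS2_kerat- > Nitric_oxide_kerat- > GUCY1A2_melan- > cGMP_melan- > PRKG1_melan- > CREB1_melan- > MITF_melan- > TYR_melan- > melanogenesis
3	alpha_msh_production	predicted		UVA- > Lipid_Peroxidation_kerat- > 4HNE_kerat- > DNA_Damage_kerat- > TP53_kerat- > alpha_MSH_kerat
3	dendrite_formation	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > KITLG_kerat- > KIT_melan- > PIK3CA_melan- > RAC1_melan- > RAC1:PARD6A:CDC42_melan- > PRKCZ_melan- > Dendrite_formation_melan
3	nfkb1_edn1_secretion	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > EDN1_kerat
3	nfkb1_csf2_secretion	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > CSF2_kerat
3	nfkb1_kitlg_secretion	predicted		UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > KITLG_kerat
3	melanocyte_proliferation	predicted		UVA- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > CSF2_kerat- > CSF2RA_melan- > CSF2RA:JAK1_melan- > STAT3_melan- > CCND1_melan- > CDK4:CCND1_melan- > Cell_proliferation_melan
3	melanosome_phagocytosis	predicted		UVA- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > F2RL1_kerat- > RHOA_kerat- > Melanosome_phagocytosis_kerat
5	melanin_synthesis	control	PTGER3_melan	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PLA2_kerat- > Arachidonic_Acid_kerat- > PGE2_kerat- > PTGER3_melan- > PLC_melan- > DAG_melan- > PRKCB_melan- > TYR_melan- > Melanogensis
5	melanin_synthesis	alternate	PTGER3_melan	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > EDN1_kerat- > EDNRB_melan- > PLC_melan- > DAG_melan- > PRKCB_melan- > TYR_melan- > Eumelanin_melan
5	melanin_synthesis	control	TYR_melan	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PLA2_kerat- > Arachidonic_Acid_kerat- > PGE2_kerat- > PTGER3_melan- > PLC_melan- > DAG_melan- > PRKCB_melan- > TYR_melan- > Melanogensis
5	melanin_synthesis	alternate	TYR_melan	None
5	dendrite_formation	control	KIT_melan	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > KITLG_kerat- > KIT_melan- > PIK3CA_melan- > RAC1_melan- > RAC1:PARD6A:CDC42_melan- > PRKCZ_melan- > Dendrite_formation_melan
5	dendrite_formation	alternate	KIT_melan	UVB- > Lipid_Peroxidation_kerat- > 4HNE_kerat- > DNA_Damage_kerat- > TP53_kerat- > ACTH_kerat- > MC1R_melan- > ADCY4_melan- > cAMP_melan- > RAP1A_melan- > RAC1_melan- > RAC1:PARD6A:CDC42_melan- > PRKCZ_melan- > Dendrite_formation_melan
5	melanosome_phagocytosis	control	F2RL1_kerat	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > F2RL1_kerat- > RHOA_kerat- > Melanosome_phagocytosis_kerat
5	melanosome_phagocytosis	alternate	F2RL1_kerat	None
5	melanocyte_proliferation	control	NFKB1_kerat	UV- > Singlet_oxygen_kerat- > Ceramide_kerat- > PRKCZ_kerat- > NFKB1_kerat- > CSF2_kerat- > CSF2RA_melan- > CSF2RA:JAK1_melan- > STAT3_melan- > CCND1_melan- > CDK4:CCND1_melan- > Cell_proliferation_melan
5	melanocyte_proliferation	alternate	NFKB1_kerat	UVB- > Lipid_Peroxidation_kerat- > 4HNE_kerat- > DNA_Damage_kerat- > TP53_kerat- > ACTH_kerat- > MC1R_melan- > ADCY4_melan- > cAMP_melan- > PRKACA_melan- > CREB1_melan- > MITF_melan- > CDK4_melan- > CDK4:CCND1_melan- > Cell_proliferation_melan
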