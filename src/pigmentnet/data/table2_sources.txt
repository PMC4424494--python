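MET_melan
EDNRB_melan
EGFR_kerat
PTGER1_melan
PTGER2_kerat
PTGER3_melan
PTGER4_kerat
FAS_kerat
FZD3_melan
CSF2RA_melan
IL1R1_kerat
IL6R_kerat
KIT_melan
MC1R_kerat
MC1R_melan
F2RL1_kerat
TNFRSF1A_kerat
NTRK1_melan
UVA
UVB
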