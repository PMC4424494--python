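Eumelanin_melan
Pheomelanin_melan
Dendrite_formation_melan
Melanosome_phagocytosis_kerat
Apoptosis_melan
Cell_proliferation_melan
Melanosome_biogenesis
Cell_survival_melan
Cell_cycle_arrest_melan
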