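Antipyrine
Caffeine
Chlorpropamide
Linezolid
Oxprenolol
Oxytetracycline
Ribavirin
Sparfloxacin
Theophylline
Tocainide
Voriconazole
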