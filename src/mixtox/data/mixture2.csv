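chemical,mass_fraction,molecular_weight
epoxiconazole,0.09,329.76
mancozeb,0.06,271.22
prochloraz,0.18,376.66
procymidone,0.35,284.14
tebuconazole,0.32,307.82
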