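chemical,mass_fraction,molecular_weight
BPA,0.005,228.29
butylparaben,0.26,194.23
DBP,0.030,278.34
DEHP,0.043,390.56
4-MBC,0.19,254.37
OMC,0.34,290.40
DDE,0.003,318.02
epoxiconazole,0.025,329.76
linuron,0.002,249.09
prochloraz,0.031,376.66
procymidone,0.044,284.14
vinclozolin,0.026,286.11
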