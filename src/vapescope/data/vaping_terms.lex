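# Vaping-term gate: a post enters the analytic sample only if it contains
# at least one of these 26 terms (after normalization).

[Vaping]
vape
vapes
vaping
vaper
vapers
vape pen
vape juice
vaporizer
vaporizers
e-cig
e-cigs
e-cigarette
e-cigarettes
ecig
ecigs
ecigarette
ecigarettes
electronic cigarette
electronic cigarettes
e-juice
e-liquid
ejuice
eliquid
juul
juuls
juuling
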