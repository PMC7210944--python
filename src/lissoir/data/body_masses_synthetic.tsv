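category	mass_kg
large bovid	700
medium ungulate	150
reindeer	100
Rangifer tarandus	100
red deer	160
Cervus elaphus	160
roe deer	25
Capreolus capreolus	25
horse	400
Equus caballus	400
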