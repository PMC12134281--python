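plant,shannon,simpson_complement,camargo,berger_parker
Agathophora alopecuroides,1.46,0.738,0.25,0.4
Anabasis setifera,1.79,0.789,0.125,0.35
Atriplex halimus,,,,
Halocnemum strobitaceum,1.39,0.75,0.25,0.25
Lantana camara,1.041,0.625,0.33,0.5
Mesembryanthemum forsskaollii,1.59,0.75,0.16,0.41
Raphanus raphanistrum,1.74,0.82,0.16,0.2
Suaeda vermiculata,1.74,0.82,0.16,0.22
Zygophyllum coccineum,1.1,0.667,0.33,0.33
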