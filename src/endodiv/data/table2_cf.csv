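plant,tissue,cf_percent
Agathophora alopecuroides,flower,
Agathophora alopecuroides,leaf,5.6
Agathophora alopecuroides,stem,5.6
Agathophora alopecuroides,root,16.6
Anabasis setifera,flower,
Anabasis setifera,leaf,8.4
Anabasis setifera,stem,14
Anabasis setifera,root,25.1
Atriplex halimus,flower,
Atriplex halimus,leaf,
Atriplex halimus,stem,
Atriplex halimus,root,
Halocnemum strobitaceum,flower,
Halocnemum strobitaceum,leaf,5.6
Halocnemum strobitaceum,stem,5.6
Halocnemum strobitaceum,root,
Lantana camara,flower,5.6
Lantana camara,leaf,
Lantana camara,stem,5.6
Lantana camara,root,
Mesembryanthemum forsskaollii,flower,19.5
Mesembryanthemum forsskaollii,leaf,5.6
Mesembryanthemum forsskaollii,stem,8.4
Mesembryanthemum forsskaollii,root,
Raphanus raphanistrum,flower,
Raphanus raphanistrum,leaf,8.4
Raphanus raphanistrum,stem,2.8
Raphanus raphanistrum,root,16.8
Suaeda vermiculata,flower,
Suaeda vermiculata,leaf,
Suaeda vermiculata,stem,
Suaeda vermiculata,root,25.0
Zygophyllum coccineum,flower,
Zygophyllum coccineum,leaf,5.6
Zygophyllum coccineum,stem,2.8
Zygophyllum coccineum,root,
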