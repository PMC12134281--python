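plant,location,tissue,morphospecies,genus,colony_count
Agathophora alopecuroides,PAWD,leaf,Aspergillus sp.1,Aspergillus,1
Agathophora alopecuroides,PAWD,stem,Chaetomium sp.,Chaetomium,1
Agathophora alopecuroides,PAWD,root,Eurotium sp.,Eurotium,1
Agathophora alopecuroides,PAWD,leaf,Trichosporon sp.,Trichosporon,1
Anabasis setifera,PAWD,leaf,Aspergillus sp.2,Aspergillus,1
Anabasis setifera,PAWD,stem,Aspergillus sp.3,Aspergillus,1
Anabasis setifera,PAWD,root,Aspergillus sp.4,Aspergillus,1
Anabasis setifera,PAWD,leaf,Fusarium sp.1,Fusarium,1
Anabasis setifera,PAWD,stem,Penicillium sp.1,Penicillium,1
Anabasis setifera,PAWD,root,Penicillium sp.2,Penicillium,1
Anabasis setifera,PAWD,leaf,Phragmocamarosporium sp.1,Phragmocamarosporium,1
Anabasis setifera,PAWD,stem,Neocosmospora sp.,Neocosmospora,1
Halocnemum strobitaceum,PAWD,leaf,Aspergillus sp.5,Aspergillus,1
Halocnemum strobitaceum,PAWD,stem,Aspergillus sp.6,Aspergillus,1
Halocnemum strobitaceum,PAWD,leaf,Phaeocremonium sp.,Phaeocremonium,1
Halocnemum strobitaceum,PAWD,stem,Talaromyces sp.,Talaromyces,1
Lantana camara,NCAH,flower,Eurotium sp.,Eurotium,1
Lantana camara,NCAH,stem,Penicillium sp.3,Penicillium,1
Lantana camara,NCAH,flower,Penicillium sp.4,Penicillium,1
Mesembryanthemum forsskaollii,PAWD,flower,Aspergillus sp.7,Aspergillus,1
Mesembryanthemum forsskaollii,PAWD,leaf,Aspergillus sp.3,Aspergillus,1
Mesembryanthemum forsskaollii,PAWD,stem,Curvularia sp.1,Curvularia,1
Mesembryanthemum forsskaollii,PAWD,flower,Phragmocamarosporium sp.2,Phragmocamarosporium,1
Mesembryanthemum forsskaollii,PAWD,leaf,Dark sterile mycelium sp.1,unclassified,1
Raphanus raphanistrum,NCAH,leaf,Aspergillus sp.8,Aspergillus,1
Raphanus raphanistrum,NCAH,stem,Aspergillus sp.3,Aspergillus,1
Raphanus raphanistrum,NCAH,root,Curvularia sp.2,Curvularia,1
Raphanus raphanistrum,NCAH,leaf,Fusarium sp.2,Fusarium,1
Raphanus raphanistrum,NCAH,stem,Penicillium sp.5,Penicillium,1
Raphanus raphanistrum,NCAH,root,Rhodotorula sp.,Rhodotorula,1
Suaeda vermiculata,PAWD,root,Curvularia sp.2,Curvularia,1
Suaeda vermiculata,PAWD,root,Diaporthe sp.,Diaporthe,1
Suaeda vermiculata,PAWD,root,Penicillium sp.6,Penicillium,1
Suaeda vermiculata,PAWD,root,Ulocladium sp.1,Ulocladium,1
Suaeda vermiculata,PAWD,root,Ulocladium sp.2,Ulocladium,1
Suaeda vermiculata,PAWD,root,Dark sterile mycelium sp.2,unclassified,1
Zygophyllum coccineum,PAWD,leaf,Aspergillus sp.7,Aspergillus,1
Zygophyllum coccineum,PAWD,stem,Aspergillus sp.3,Aspergillus,1
Zygophyllum coccineum,PAWD,leaf,Quambalaria sp.,Quambalaria,1
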