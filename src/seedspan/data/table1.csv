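species,family,order,endosperm,pretreatment,dormancy,germ_temp,p50,p50_se,rank
Achillea millefolium,Asteraceae,Asterales,N,none,ND,22/22,46.7,1.4,14
Acinos arvensis,Lamiaceae,Lamiales,N,none,ND,22/14,28.6,1,24
Anthericum ramosum,Asparagaceae,Liliales,E,STRAT,PD,22/14,45.6,1.2,15
Anthyllis vulneraria,Fabaceae,Fabales,N,SCAR,PY,22/14,198.2,8.4,2
Arabis hirsuta,Brassicaceae,Brassicales,N,none,ND,22/14,63.4,1.6,9
Arenaria serpyllifolia,Caryophyllaceae,Caryophyllales,N,none,ND,22/14,54.3,1.5,12
Asperula cynanchica,Rubiaceae,Gentianales,E,STRAT,PD,22/14,16.2,0.5,31
Briza media,Poaceae,Poales,E,none,ND,22/14,14.8,0.7,32
Bromus erectus,Poaceae,Poales,E,none,ND,22/14,29.3,1.1,22
Buphthalmum salicifolium,Asteraceae,Asterales,N,none,ND,26/18,82.6,1.9,7
Campanula rotundifolia,Campanulaceae,Asterales,E,none,ND,22/14,10.8,0.5,36
Carduus nutans,Asteraceae,Asterales,N,none,ND,22/14,28.4,0.8,25
Carex flacca,Cyperaceae,Poales,E,STRAT,PD,22/14,13.7,0.9,34
Centaurea stoebe,Asteraceae,Asterales,N,none,ND,22/22,52,1.7,13
Cerastium arvense,Caryophyllaceae,Caryophyllales,N,none,ND,14/6,55.7,1.5,11
Daucus carota,Apiaceae,Apiales,E,none,ND,22/14,44.2,1.7,17
Dianthus carthusianorum,Caryophyllaceae,Caryophyllales,N,none,ND,22/14,42.3,1.2,19
Galium verum,Rubiaceae,Gentianales,E,STRAT,PD,22/14,16.4,1,30
Genista tinctoria,Fabaceae,Fabales,N,SCAR,PY,22/14,73.6,3.1,8
Globularia bisnagarica,Plantaginaceae,Lamiales,N,STRAT,PD,22/14,14.8,1.1,33
Helianthemum nummularium,Cistaceae,Malvales,N,SCAR,PY,22/14,155,4,6
Hypericum perforatum,Clusiaceae,Malpighiales,N,none,ND,22/14,29.9,1,21
Linum catharticum,Linaceae,Malpighiales,N,GA3,PD,22/14,43.5,1.9,18
Lotus corniculatus,Fabaceae,Fabales,N,SCAR,PY,22/14,197.9,5.8,4
Medicago lupulina,Fabaceae,Fabales,N,SCAR,PY,22/14,198.1,35933.4,3
Melica ciliata,Poaceae,Poales,E,none,ND,22/14,21.9,341.8,28
Phleum phleoides,Poaceae,Poales,E,none,ND,22/14,25,0.8,27
Pimpinella saxifraga,Apiaceae,Apiales,E,STRAT,PD,22/14,4.9,0.4,38
Prunella grandiflora,Lamiaceae,Lamiales,N,none,ND,18/10,57.2,1.6,10
Pulsatilla vulgaris,Ranunculaceae,Ranunculales,E,none,ND,26/18,31.3,1.6,20
Rhinanthus minor,Scrophulariaceae,Lamiales,E,STRAT,PD,22/14,3.4,0.2,39
Scabiosa columbaria,Dipsacaceae,Dipsacales,N,none,ND,22/14,18.8,0.8,29
Seseli annuum,Apiaceae,Apiales,E,STRAT,PD,22/14,5.4,0.6,37
Stachys recta,Lamiaceae,Lamiales,N,GA3,PD,22/14,45.1,1.6,16
Teucrium chamaedrys,Lamiaceae,Lamiales,N,GA3,PD,22/14,29.2,1.4,23
Teucrium montanum,Lamiaceae,Lamiales,N,GA3,PD,22/14,25.7,0.5,26
Thymus pulegioides,Lamiaceae,Lamiales,N,none,ND,22/14,12.4,0.5,35
Trifolium arvense,Fabaceae,Fabales,N,SCAR,PY,22/14,282.2,26,1
Trifolium montanum,Fabaceae,Fabales,N,SCAR,PY,22/14,165.8,5.9,5
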