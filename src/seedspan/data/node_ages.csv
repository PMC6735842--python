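taxon,age_myr
root,160
Asterales,93
Lamiales,106
Liliales,117
Fabales,94
Brassicales,71
Caryophyllales,104
Gentianales,108
Poales,113
Apiales,87
Malvales,68
Malpighiales,91
Ranunculales,122
Dipsacales,92
Asteraceae,49
Campanulaceae,55
Lamiaceae,62
Plantaginaceae,66
Scrophulariaceae,60
Asparagaceae,80
Fabaceae,79
Brassicaceae,54
Caryophyllaceae,70
Rubiaceae,78
Poaceae,83
Cyperaceae,76
Apiaceae,67
Cistaceae,50
Clusiaceae,72
Linaceae,70
Ranunculaceae,108
Dipsacaceae,70
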