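fragment_id,area,perimeter,isolation,cover,richness,specialist_richness,individuals
Mbololo,178.79,9980,0.39,46.2,24,10,1797
Ngangao,146.93,11529,0.54,48.6,39,12,7179
Chawia,90.25,5291,0.37,42.0,38,13,4066
Ronge,14.81,2035,0.33,36.4,17,7,219
Fururu,8.04,1495,0.53,5.1,30,9,1492
Vuria,6.99,1099,0.18,18.0,14,8,78
Yale,3.94,897,0.56,6.1,15,9,330
Ndiwenyi,3.76,893,0.53,4.4,27,10,898
Macha,3.42,1728,0.56,2.1,32,10,1054
Mwachora,2.31,606,0.25,2.0,13,5,239
Kichuchenyi,1.28,514,0.53,1.1,6,4,13
Wundanyi,1.14,455,0.50,1.6,13,4,166
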