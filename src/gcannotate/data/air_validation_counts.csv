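compound,total_detected,level3_all,level2_all,level2_ri,level2_rsi,level2_rhrmf,molecular_ion,correct_level2_retained,correct_molecular_ion_observed
Benz[a]anthracene,25,14,3,5,18,16,11,yes,yes
Chrysene,39,19,3,4,33,24,11,yes,yes
Fluoranthene,54,28,9,12,34,43,6,yes,yes
Fluorene,33,29,7,9,32,29,7,yes,yes
Acenaphthylene,33,23,7,12,33,23,5,yes,yes
Naphthalene,40,32,8,11,40,32,9,yes,yes
Phenanthrene,38,38,7,7,38,38,13,yes,yes
Pyrene,53,23,7,7,36,34,6,yes,yes
2-Chloronaphthalene,27,13,2,6,27,13,3,yes,yes
Dibenzofuran,49,29,5,16,48,29,12,yes,yes
Hexachlorobenzene,32,9,6,12,31,9,5,yes,yes
Hexachlorobutadiene,32,2,1,2,26,2,1,yes,yes
Tris(1-chloro-2-propyl) phosphate,20,5,3,7,17,7,0,no,no
"4,4'-Dibromooctafluorobiphenyl",27,1,1,2,27,1,1,yes,yes
Isophorone,49,46,19,19,49,46,8,yes,yes
N-Nitrosodiphenylamine,46,35,4,4,46,35,23,no,no
Butylbenzyl phthalate,21,7,4,7,18,7,3,yes,no
Diethyl phthalate,28,18,4,6,27,18,0,yes,no
Di-n-octyl phthalate,53,45,9,10,52,45,1,no,no
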