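year,salmon_biomass
0,-0.039061006276415636
1,1.4223597197951088
2,1.2734933932256314
3,-0.6393706830987473
4,-0.40526906337124813
5,-0.6581981598129171
6,0.5513633988913615
7,-0.13856934395016365
8,0.7466810256840101
9,-2.1134292810866198
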