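class_code,name,natural,economic,social
1,cultivated,16453,6250,10000
2,garden,17082,8630,0
3,forest,30011,430,1650
4,grassland,19110,330,1650
5,construction,0,1000,58594
6,aml,0,0,0
7,water,12803,68880,1600
8,unutilized,11906,0,0
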