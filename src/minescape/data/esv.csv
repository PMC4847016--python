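class_code,name,esv
1,cultivated,3296.98
2,garden,7516.28
3,forest,11735.57
4,grassland,4870.35
5,construction,0
6,aml,0
7,water,18926.32
8,unutilized,580.10
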