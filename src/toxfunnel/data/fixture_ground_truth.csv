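id,amines,alkyl_amines,aromatic_nitrogens,basic_nitrogens
benzene,0,0,0,0
pyridine,0,0,1,1
pyrrole,0,0,1,0
imidazole,0,0,2,1
pyrimidine,0,0,2,2
ethylamine,1,1,0,1
diethylamine,1,1,0,1
triethylamine,1,1,0,1
ethylenediamine,2,2,0,2
aniline,0,0,0,0
acetamide,0,0,0,0
benzamide,0,0,0,0
piperidine,1,1,0,1
morpholine,1,1,0,1
piperazine,2,2,0,2
quinoline,0,0,1,1
allylamine,1,1,0,1
benzylamine,1,1,0,1
nitrobenzene,0,0,0,0
nicotine,1,1,1,2
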