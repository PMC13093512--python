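region,cytoarch_class
bankssts,AC2
caudalanteriorcingulate,LIMB
caudalmiddlefrontal,AC1
cuneus,SSC
entorhinal,LIMB
frontalpole,AC1
fusiform,AC2
inferiorparietal,AC1
inferiortemporal,AC2
insula,INS
isthmuscingulate,LIMB
lateraloccipital,SSC
lateralorbitofrontal,AC1
lingual,SSC
medialorbitofrontal,AC1
middletemporal,AC1
paracentral,PMC
parahippocampal,LIMB
parsopercularis,AC1
parsorbitalis,AC1
parstriangularis,AC1
pericalcarine,PSC
postcentral,PSC
posteriorcingulate,LIMB
precentral,PMC
precuneus,AC2
rostralanteriorcingulate,LIMB
rostralmiddlefrontal,AC1
superiorfrontal,AC1
superiorparietal,SSC
superiortemporal,AC1
supramarginal,AC1
temporalpole,LIMB
transversetemporal,PSC
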