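koppen,gez_id,gez_name
Af,11,tropical rainforest
Am,12,tropical moist forest
Aw,13,tropical dry forest
As,13,tropical dry forest
BSh,14,tropical shrubland
BSh,23,subtropical steppe
BWh,15,tropical desert
BWh,24,subtropical desert
BSk,33,temperate steppe
BWk,34,temperate desert
Csa,22,subtropical dry forest
Csb,22,subtropical dry forest
Cfa,21,subtropical humid forest
Cwa,21,subtropical humid forest
Cwb,25,subtropical mountain system
Cwc,25,subtropical mountain system
Cfb,31,temperate oceanic forest
Cfc,31,temperate oceanic forest
Dfa,32,temperate continental forest
Dfb,32,temperate continental forest
Dwa,32,temperate continental forest
Dwb,32,temperate continental forest
Dsa,33,temperate steppe
Dsb,33,temperate steppe
Dsc,35,temperate mountain system
Dfc,41,boreal coniferous forest
Dwc,41,boreal coniferous forest
Dfd,42,boreal tundra woodland
Dwd,42,boreal tundra woodland
Dsd,43,boreal mountain system
H,16,tropical mountain system
H,25,subtropical mountain system
H,35,temperate mountain system
H,43,boreal mountain system
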