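cultivar,substrate_volume,plants_per_slab,brix_mean
Dalgona,10,3,14.5
Dalgona,10,4,13.9
Dalgona,20,3,13.7
Dalgona,20,4,13.5
Hero,10,3,14.3
Hero,10,4,13.7
Hero,20,3,13.3
Hero,20,4,12.9
Kingstar,10,3,11.4
Kingstar,10,4,11.0
Kingstar,20,3,10.2
Kingstar,20,4,10.1
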