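substrate_volume,plants_per_slab,planting_distance_cm,row_spacing_cm,plant_density_reported,plants_per_10a
10,3,30,150,2.2,2222
10,4,22.5,150,3.0,2963
20,3,100/3,150,2.0,2000
20,4,25,150,2.7,2667
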