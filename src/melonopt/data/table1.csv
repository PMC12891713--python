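cultivar,substrate_volume,plants_per_slab,total_yield,yield_letter,water_productivity,wp_letter,fertilizer_cost,substrate_cost
Dalgona,10,3,2712,c,4.1,a,804.8,1085.4
Dalgona,10,4,3466,a,3.3,c,1085.4,1085.4
Dalgona,20,3,2477,d,3.7,b,804.8,1392.9
Dalgona,20,4,3141,b,3.1,d,1085.4,1392.9
Hero,10,3,3552,c,5.4,a,804.8,1085.4
Hero,10,4,4339,a,4.2,c,1085.4,1085.4
Hero,20,3,3225,d,4.8,b,804.8,1392.9
Hero,20,4,3846,b,3.8,d,1085.4,1392.9
Kingstar,10,3,3735,a,5.7,a,804.8,1085.4
Kingstar,10,4,4161,a,4.0,c,1085.4,1085.4
Kingstar,20,3,3220,b,4.8,b,804.8,1392.9
Kingstar,20,4,4101,a,4.1,c,1085.4,1392.9
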