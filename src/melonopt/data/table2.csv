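cultivar,substrate_volume,plants_per_slab,length,length_letter,diameter,diameter_letter,shape_index,shape_letter,net_score,net_letter,flesh_thickness,flesh_letter
Dalgona,10,3,13.7,a,13.4,a,1.01,a,1.3,a,40.6,a
Dalgona,10,4,13.1,d,13.1,c,0.99,c,1.2,a,39.6,a
Dalgona,20,3,13.6,b,13.4,a,1.01,a,1.4,a,40.2,a
Dalgona,20,4,13.3,c,13.2,b,1.00,b,1.5,a,35.3,b
Hero,10,3,15.5,b,14.3,b,1.10,a,1.3,a,43.0,a
Hero,10,4,14.9,d,13.8,c,1.09,a,1.2,a,40.1,cd
Hero,20,3,16.0,a,14.4,a,1.07,a,1.4,a,41.0,b
Hero,20,4,15.1,c,13.8,cd,1.09,a,1.4,a,40.3,c
Kingstar,10,3,15.6,a,14.5,a,1.08,a,1.4,a,39.7,a
Kingstar,10,4,14.6,b,14.0,b,1.03,c,1.6,a,39.3,a
Kingstar,20,3,15.3,a,14.4,a,1.07,a,1.5,a,40.8,a
Kingstar,20,4,15.0,a,14.3,a,1.05,b,1.5,a,40.0,a
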