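species,E_eV,r_squared,p,assay_temps_C,mean_weight_g,environment
Redband trout,0.59,0.57,<0.001,"12,15,18,21,24",1.14,F
Redband trout,0.58,0.53,<0.001,"12,15,18,21,24",2.41,F
Redband trout,0.56,0.49,<0.001,"12,15,18,21,24",3.4,F
Goby,0.32,0.28,<0.001,"15,22,28,33,36",1.15,"M,B"
Goby,0.61,0.3,<0.001,"15,22,28,33,36",0.73,"M,B"
Black sea bass,0.69,0.74,<0.001,"24,27,30",265.6,M
Black sea bass,0.56,0.87,<0.001,"12,17,22,27,30",375,M
Mosquitofish,0.31,0.04,0.0052,"24.8,29.6,34.9,35.5,37.15",0.57,"F,B"
Mosquitofish,0.23,0.02,0.062,"19.2,22.4,23.7,27.6,29.97",0.38,"F,B"
Nile tilapia,0.96,0.95,<0.001,"19,22,25,28,31",50,"F,B"
Nile tilapia,0.86,,<0.001,"19,22,25,28,31",200,"F,B"
Atlantic killifish,0.6,0.85,<0.001,"5,10,15,20,25,30,33",4.58,"M,B,F"
Atlantic killifish,0.73,0.81,<0.001,"5,10,15,20,25,30,33",6.14,"M,B,F"
Atlantic killifish,0.51,0.9,<0.001,"5,10,15,20,25,30,33",6.26,"M,B,F"
Atlantic killifish,0.6,0.91,<0.001,"5,10,15,20,25,30,33",6.77,"M,B,F"
Atlantic salmon,0.55,0.9,<0.001,"3,8,13,18,23",443.77,"M,B,F"
Lumpfish,0.37,0.54,<0.001,"3,9,15",310.21,M
Ballan wrasse,0.62,0.14,<0.001,"5,10,15,20,23",162.59,F
Roach,0.6,0.24,<0.001,"5,10,15,20,23",63.76,"B,F"
Vendace,0.64,0.4,<0.001,"4,8,15",30.78,"M,B,F"
Stechlin cisco,0.54,0.44,<0.001,"4,8,15",16.15,F
Polar cod,0.33,0.42,<0.001,"0,3,6,8",16,M
Atlantic cod,0.4,0.68,<0.001,"3,8,12,16",40.76,M
Atlantic cod,0.46,0.63,<0.001,"8,20",73,M
Atlantic cod,0.37,0.51,<0.001,"12,23",64.6,M
Bonefish,0.37,0.1,0.013,"22,35",,M
Qingbo,0.4,0.71,<0.001,"10,15,20,25,30",2.87,F
Thorny skate,0.7,0.33,0.0018,"5,9,13",1.56,M
Clearnose skate,0.44,0.26,0.01,"20,24,28",1.22,M
Snakehead,0.81,0.95,<0.001,"15,20,25,30,35",4.4,F
Snakehead,0.72,0.91,<0.001,"15,20,25,30,35",4.42,F
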